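"""Report rendering: agreement and screening tables, CSV and markdown.

Two tables mirror the shape clinicians expect from a method-comparison
study:

* the agreement table — one row per frequency for the index-vs-reference
  comparison and one per retest frequency for test-retest, with bias,
  limits of agreement (each with 95% CI), ICC with CI and the
  bias-vs-mean Pearson r;
* the screening table — sensitivity and specificity (%, exact 95% CI) per
  frequency plus the combined screening-frequency row.

Formatting is deterministic: 2 decimal places, ASCII hyphens, fixed column
order, so identical inputs give byte-identical files.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .stats import StudySummary, format_p

logger = logging.getLogger(__name__)

__all__ = [
    "ReportError",
    "agreement_table",
    "screening_table",
    "render_tables",
    "to_markdown",
]


class ReportError(RuntimeError):
    """Refusal to render: empty or partial statistics."""


def _ci(pair: tuple[float, float]) -> str:
    return f"({pair[0]:.2f} to {pair[1]:.2f})"


def agreement_table(summary: StudySummary) -> pd.DataFrame:
    """Agreement rows: index vs reference per frequency, then test-retest."""
    rows = []
    for comparison, ba_map, icc_map in (
        ("index_vs_reference", summary.agreement, summary.agreement_icc),
        ("test_retest", summary.trt, summary.trt_icc),
    ):
        for f in sorted(ba_map):
            ba = ba_map[f]
            icc = icc_map.get(f)
            pcc = summary.agreement_pcc.get(f) if comparison == "index_vs_reference" else None
            rows.append(
                {
                    "comparison": comparison,
                    "frequency_hz": f,
                    "n": ba.n,
                    "bias_db": f"{ba.bias:.2f}",
                    "bias_ci": _ci(ba.bias_ci),
                    "lloa_db": f"{ba.lloa:.2f}",
                    "lloa_ci": _ci(ba.lloa_ci),
                    "uloa_db": f"{ba.uloa:.2f}",
                    "uloa_ci": _ci(ba.uloa_ci),
                    "icc": f"{icc.icc_agreement:.2f}" if icc else "N/A",
                    "icc_ci": _ci(icc.agreement_ci) if icc else "N/A",
                    "pcc_r": f"{pcc.r:.2f}" if pcc and pcc.defined else "N/A",
                }
            )
    return pd.DataFrame(rows)


def screening_table(summary: StudySummary) -> pd.DataFrame:
    """Screening accuracy rows per frequency plus the combined row."""
    rows = []
    for f in sorted(summary.diagnostics_by_frequency):
        d = summary.diagnostics_by_frequency[f]
        rows.append(
            {
                "frequency_hz": str(f),
                "sensitivity_pct": f"{d.sensitivity:.2f}" if d.sensitivity_defined else "N/A",
                "sensitivity_ci": _ci(d.sensitivity_ci) if d.sensitivity_defined else "N/A",
                "specificity_pct": f"{d.specificity:.2f}" if d.specificity_defined else "N/A",
                "specificity_ci": _ci(d.specificity_ci) if d.specificity_defined else "N/A",
            }
        )
    s = summary.screening
    label = "screening (" + ", ".join(
        str(f) for f in summary.labels.screening_frequencies
    ) + ")"
    rows.append(
        {
            "frequency_hz": label,
            "sensitivity_pct": f"{s.sensitivity:.2f}" if s.sensitivity_defined else "N/A",
            "sensitivity_ci": _ci(s.sensitivity_ci) if s.sensitivity_defined else "N/A",
            "specificity_pct": f"{s.specificity:.2f}" if s.specificity_defined else "N/A",
            "specificity_ci": _ci(s.specificity_ci) if s.specificity_defined else "N/A",
        }
    )
    return pd.DataFrame(rows)


def to_markdown(df: pd.DataFrame) -> str:
    """Minimal GitHub-style markdown table (no external dependency)."""
    cols = list(df.columns)
    lines = ["| " + " | ".join(cols) + " |", "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(str(row[c]) for c in cols) + " |")
    return "\n".join(lines) + "\n"


def render_tables(
    summary: StudySummary,
    outdir: str | Path,
    allow_partial: bool = False,
) -> dict[str, Path]:
    """Write the agreement and screening tables as CSV and markdown.

    Refuses partial statistics (an undefined screening metric, or a
    missing test-retest block) unless ``allow_partial`` is set. Returns the
    paths written.
    """
    agreement = agreement_table(summary)
    screening = screening_table(summary)
    if agreement.empty or screening.empty:
        raise ReportError("no statistics to render")
    partial = (
        not summary.screening.sensitivity_defined
        or not summary.screening.specificity_defined
        or not summary.trt
    )
    if partial and not allow_partial:
        raise ReportError(
            "statistics are partial (undefined screening metric or missing "
            "retest block); pass allow_partial to render anyway"
        )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (("agreement", agreement), ("screening", screening)):
        csv_path = outdir / f"{name}_table.csv"
        md_path = outdir / f"{name}_table.md"
        df.to_csv(csv_path, index=False)
        md_path.write_text(to_markdown(df))
        paths[f"{name}_csv"] = csv_path
        paths[f"{name}_md"] = md_path

    extra = [
        f"n_pairs: {summary.n_pairs}",
        f"n_pairs_excluded: {summary.n_pairs_excluded}",
        f"within_tolerance: {summary.tolerance.n_within}/{summary.tolerance.n_total} "
        f"({100 * summary.tolerance.proportion:.2f}% within {summary.tolerance.tolerance:g} dB)",
        f"mean_lloa_db: {summary.aggregate.mean_lloa:.2f} (SD {summary.aggregate.sd_lloa:.2f})",
        f"mean_uloa_db: {summary.aggregate.mean_uloa:.2f} (SD {summary.aggregate.sd_uloa:.2f})",
    ]
    if summary.fp_test is not None:
        extra.append(
            f"false_positive_t: t={summary.fp_test.t:.2f}, "
            f"p={format_p(summary.fp_test.p_value)}"
        )
    summary_path = outdir / "summary.txt"
    summary_path.write_text("\n".join(extra) + "\n")
    paths["summary"] = summary_path
    logger.info("wrote report tables to %s", outdir)
    return paths
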