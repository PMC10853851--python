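"""Agreement and diagnostic-accuracy statistics.

The battery applied to paired threshold measurements:

* Bland-Altman bias and 95% limits of agreement (LoA), each with a
  Student-t confidence interval (bias SE = s/sqrt(n); LoA SE =
  s*sqrt(3/n), the classical approximation),
* two-way single-measure intraclass correlations — absolute agreement
  ICC(A,1) and consistency ICC(C,1) — from the two-way ANOVA mean squares,
  with F-based confidence intervals,
* Pearson correlation (used between the per-pair bias and mean),
* the fraction of pairs within a clinical tolerance (|diff| <= 10 dB),
* exact (Clopper-Pearson) binomial confidence intervals and
  sensitivity/specificity from screening labels,
* a two-sample Student t test (pooled by default, Welch by flag) for
  false-positive counts,

plus :func:`summarize_study`, which runs the whole battery on a
:class:`~puretone.harness.StudyDataset`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .harness import ScreeningLabels, StudyDataset, classify_screening

__all__ = [
    "BlandAltmanResult",
    "AggregateLoA",
    "ICCResult",
    "PearsonResult",
    "ToleranceResult",
    "DiagnosticResult",
    "TTestResult",
    "StudySummary",
    "bland_altman",
    "aggregate_loa",
    "icc_two_way",
    "pearson_r",
    "within_tolerance",
    "clopper_pearson",
    "diagnostic_accuracy",
    "two_sample_t",
    "two_sample_t_from_stats",
    "summarize_study",
]


# ---------------------------------------------------------------------------
# Bland-Altman

@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias, SD of differences and limits of agreement, all with 95% CIs.

    Differences are taken b - a; ``lloa = bias - z*sd_diff`` and
    ``uloa = bias + z*sd_diff``, so ``lloa + uloa == 2*bias`` exactly.
    """

    n: int
    bias: float
    sd_diff: float
    lloa: float
    uloa: float
    bias_ci: tuple[float, float]
    lloa_ci: tuple[float, float]
    uloa_ci: tuple[float, float]


def bland_altman(
    a: Sequence[float],
    b: Sequence[float],
    z: float = 1.96,
    conf: float = 0.95,
) -> BlandAltmanResult:
    """Bland-Altman agreement between paired measurements ``a`` and ``b``.

    CI half-widths use the t quantile on n-1 df: ``t * s / sqrt(n)`` for
    the bias and ``t * s * sqrt(3/n)`` for each limit of agreement. A
    degenerate sample (all differences equal) yields zero-width CIs.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-d and the same length")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 pairs for confidence intervals")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in input")

    d = b - a
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    lloa = bias - z * sd
    uloa = bias + z * sd
    t = float(sps.t.ppf(0.5 + conf / 2.0, n - 1))
    half_bias = t * sd / math.sqrt(n)
    half_loa = t * sd * math.sqrt(3.0 / n)
    return BlandAltmanResult(
        n=n,
        bias=bias,
        sd_diff=sd,
        lloa=lloa,
        uloa=uloa,
        bias_ci=(bias - half_bias, bias + half_bias),
        lloa_ci=(lloa - half_loa, lloa + half_loa),
        uloa_ci=(uloa - half_loa, uloa + half_loa),
    )


@dataclass(frozen=True)
class AggregateLoA:
    """Mean and sample SD of lower/upper LoAs across frequencies."""

    mean_lloa: float
    sd_lloa: float
    mean_uloa: float
    sd_uloa: float


def aggregate_loa(results: Sequence[BlandAltmanResult]) -> AggregateLoA:
    """Aggregate per-frequency limits of agreement (mean and n-1 SD)."""
    if len(results) < 2:
        raise ValueError("need at least 2 results to aggregate")
    lloa = np.array([r.lloa for r in results], dtype=float)
    uloa = np.array([r.uloa for r in results], dtype=float)
    return AggregateLoA(
        mean_lloa=float(lloa.mean()),
        sd_lloa=float(lloa.std(ddof=1)),
        mean_uloa=float(uloa.mean()),
        sd_uloa=float(uloa.std(ddof=1)),
    )


# ---------------------------------------------------------------------------
# Intraclass correlation

def _icc_band(value: float) -> str:
    if value >= 0.90:
        return "excellent"
    if value >= 0.75:
        return "good"
    if value >= 0.50:
        return "moderate"
    return "poor"


@dataclass(frozen=True)
class ICCResult:
    """Two-way single-measure ICCs with F-based 95% CIs and mean squares."""

    n_subjects: int
    n_raters: int
    icc_agreement: float
    icc_consistency: float
    agreement_ci: tuple[float, float]
    consistency_ci: tuple[float, float]
    ms_subjects: float
    ms_raters: float
    ms_error: float
    degenerate: bool = False

    @property
    def agreement_band(self) -> str:
        return _icc_band(self.icc_agreement)

    @property
    def consistency_band(self) -> str:
        return _icc_band(self.icc_consistency)


def icc_two_way(matrix: Sequence[Sequence[float]], conf: float = 0.95) -> ICCResult:
    """Two-way single-measure ICCs from a subjects x raters matrix.

    Computes ICC(A,1) (absolute agreement; two-way random/mixed) and
    ICC(C,1) (consistency) from the two-way ANOVA mean squares, with the
    standard F-based confidence intervals (Satterthwaite df for the
    agreement form). A matrix with zero total variance is degenerate: both
    ICCs are defined as 1 with zero-width CIs.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("need a 2-d matrix with >= 3 subjects and >= 2 raters")
    if not np.isfinite(x).all():
        raise ValueError("matrix contains non-finite values (no missing cells allowed)")
    n, k = x.shape

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols

    if ss_total <= 1e-12:
        return ICCResult(
            n_subjects=n, n_raters=k,
            icc_agreement=1.0, icc_consistency=1.0,
            agreement_ci=(1.0, 1.0), consistency_ci=(1.0, 1.0),
            ms_subjects=0.0, ms_raters=0.0, ms_error=0.0,
            degenerate=True,
        )

    msr = ss_rows / (n - 1)          # between-subject
    msc = ss_cols / (k - 1)          # between-rater
    mse = ss_err / ((n - 1) * (k - 1))

    icc_c = (msr - mse) / (msr + (k - 1) * mse)
    icc_a = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))

    alpha = 1.0 - conf
    # consistency CI: exact F interval
    if mse > 0:
        f_obs = msr / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = f_obs / sps.f.ppf(1 - alpha / 2, df1, df2)
        fu = f_obs * sps.f.ppf(1 - alpha / 2, df2, df1)
        ci_c = ((fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1))
    else:
        ci_c = (1.0, 1.0)

    # agreement CI: McGraw & Wong with Satterthwaite df; when the df
    # estimate collapses to ~0 the F quantile diverges and the bound is the
    # f -> inf limit of the interval formula
    if mse > 0 and icc_a < 1.0:
        a_coef = (k * icc_a) / (n * (1 - icc_a))
        b_coef = 1 + (k * icc_a * (n - 1)) / (n * (1 - icc_a))
        v = (a_coef * msc + b_coef * mse) ** 2 / (
            (a_coef * msc) ** 2 / (k - 1)
            + (b_coef * mse) ** 2 / ((n - 1) * (k - 1))
        )
        if not math.isfinite(v) or v <= 0:
            v = 1e-10
        f_star_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f_star_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
        mix = k * msc + (k * n - k - n) * mse
        if math.isfinite(f_star_l):
            lo_a = n * (msr - f_star_l * mse) / (f_star_l * mix + n * msr)
        else:
            lo_a = -n * mse / mix if mix > 0 else -1.0
        if math.isfinite(f_star_u) and f_star_u > 0:
            hi_a = n * (f_star_u * msr - mse) / (mix + n * f_star_u * msr)
        else:
            hi_a = 1.0
        lo_a = max(min(lo_a, icc_a), -1.0)
        hi_a = min(max(hi_a, icc_a), 1.0)
        ci_a = (lo_a, hi_a)
    else:
        ci_a = (1.0, 1.0)

    return ICCResult(
        n_subjects=n, n_raters=k,
        icc_agreement=float(icc_a), icc_consistency=float(icc_c),
        agreement_ci=(float(ci_a[0]), float(ci_a[1])),
        consistency_ci=(float(ci_c[0]), float(ci_c[1])),
        ms_subjects=float(msr), ms_raters=float(msc), ms_error=float(mse),
    )


# ---------------------------------------------------------------------------
# Pearson correlation

@dataclass(frozen=True)
class PearsonResult:
    r: float
    p_value: float
    n: int
    defined: bool = True


def pearson_r(x: Sequence[float], y: Sequence[float]) -> PearsonResult:
    """Product-moment correlation with two-sided p (t transform).

    Zero variance in either variable leaves the coefficient undefined; the
    result is flagged rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be 1-d, equal length, n >= 3")
    if x.std() == 0 or y.std() == 0:
        return PearsonResult(r=float("nan"), p_value=float("nan"), n=x.size, defined=False)
    res = sps.pearsonr(x, y)
    return PearsonResult(r=float(res.statistic), p_value=float(res.pvalue), n=x.size)


# ---------------------------------------------------------------------------
# Tolerance proportion

@dataclass(frozen=True)
class ToleranceResult:
    n_within: int
    n_total: int
    tolerance: float

    @property
    def proportion(self) -> float:
        return self.n_within / self.n_total


def within_tolerance(
    a: Sequence[float], b: Sequence[float], tol: float = 10.0
) -> ToleranceResult:
    """Fraction of pairs whose absolute difference is within ``tol`` (inclusive)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 1:
        raise ValueError("a and b must be equal-length and non-empty")
    within = int(np.sum(np.abs(b - a) <= tol))
    return ToleranceResult(n_within=within, n_total=int(a.size), tolerance=tol)


# ---------------------------------------------------------------------------
# Exact binomial CI and diagnostic accuracy

def clopper_pearson(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial CI for x/n, in percent.

    Beta-quantile form: lower = Beta(alpha/2; x, n-x+1), upper =
    Beta(1-alpha/2; x+1, n-x); lower is 0 when x = 0 and upper is 100 when
    x = n.
    """
    if not isinstance(x, (int, np.integer)) or not isinstance(n, (int, np.integer)):
        raise ValueError("x and n must be integers")
    if n < 1 or not 0 <= x <= n:
        raise ValueError("require 0 <= x <= n and n >= 1")
    alpha = 1.0 - conf
    lo = 0.0 if x == 0 else float(sps.beta.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(sps.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return 100.0 * lo, 100.0 * hi


@dataclass(frozen=True)
class DiagnosticResult:
    """Confusion counts and sensitivity/specificity (%) with exact 95% CIs.

    When one class is absent the corresponding metric is undefined:
    reported as NaN with the matching ``*_defined`` flag False.
    """

    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float
    specificity: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    sensitivity_defined: bool = True
    specificity_defined: bool = True


def diagnostic_accuracy(
    truth: Sequence[bool], prediction: Sequence[bool], conf: float = 0.95
) -> DiagnosticResult:
    """Sensitivity and specificity of a binary screen, with exact CIs."""
    truth = np.asarray(truth, dtype=bool)
    prediction = np.asarray(prediction, dtype=bool)
    if truth.shape != prediction.shape or truth.ndim != 1 or truth.size < 1:
        raise ValueError("truth and prediction must be equal-length 1-d")
    tp = int(np.sum(truth & prediction))
    fn = int(np.sum(truth & ~prediction))
    tn = int(np.sum(~truth & ~prediction))
    fp = int(np.sum(~truth & prediction))

    if tp + fn > 0:
        sens = 100.0 * tp / (tp + fn)
        sens_ci = clopper_pearson(tp, tp + fn, conf)
        sens_def = True
    else:
        sens, sens_ci, sens_def = float("nan"), (float("nan"), float("nan")), False
    if tn + fp > 0:
        spec = 100.0 * tn / (tn + fp)
        spec_ci = clopper_pearson(tn, tn + fp, conf)
        spec_def = True
    else:
        spec, spec_ci, spec_def = float("nan"), (float("nan"), float("nan")), False

    return DiagnosticResult(
        tp=tp, fn=fn, tn=tn, fp=fp,
        sensitivity=sens, specificity=spec,
        sensitivity_ci=sens_ci, specificity_ci=spec_ci,
        sensitivity_defined=sens_def, specificity_defined=spec_def,
    )


# ---------------------------------------------------------------------------
# Two-sample t test

@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p_value: float
    degenerate: bool = False


def two_sample_t(
    a: Sequence[float], b: Sequence[float], welch: bool = False
) -> TTestResult:
    """Two-sample t test (pooled Student by default; Welch by flag)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return TTestResult(t=0.0, df=a.size + b.size - 2, p_value=1.0)
        return TTestResult(
            t=float("inf") if b.mean() < a.mean() else float("-inf"),
            df=a.size + b.size - 2, p_value=0.0, degenerate=True,
        )
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return TTestResult(t=float(res.statistic), df=float(res.df), p_value=float(res.pvalue))


def two_sample_t_from_stats(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
    welch: bool = False,
) -> TTestResult:
    """Two-sample t from summary statistics (means, SDs, sizes)."""
    res = sps.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=not welch
    )
    df = n_a + n_b - 2 if not welch else float("nan")
    return TTestResult(t=float(res.statistic), df=df, p_value=float(res.pvalue))


# ---------------------------------------------------------------------------
# Whole-study summary

def format_p(p: float) -> str:
    """Render a p-value to 3 dp with a '<.001' floor."""
    if math.isnan(p):
        return "N/A"
    if p < 0.001:
        return "<.001"
    return f"{p:.3f}"


@dataclass
class StudySummary:
    """Everything the report tables need, computed from one StudyDataset."""

    agreement: dict[int, BlandAltmanResult]
    agreement_icc: dict[int, ICCResult]
    agreement_pcc: dict[int, PearsonResult]
    trt: dict[int, BlandAltmanResult]
    trt_icc: dict[int, ICCResult]
    aggregate: AggregateLoA
    aggregate_trt: AggregateLoA | None
    tolerance: ToleranceResult
    tolerance_trt: ToleranceResult | None
    diagnostics_by_frequency: dict[int, DiagnosticResult]
    screening: DiagnosticResult
    labels: ScreeningLabels
    fp_test: TTestResult | None
    fp_reference: list[int]
    fp_index: list[int]
    n_pairs: int
    n_pairs_excluded: int


def _paired(df: pd.DataFrame, method_a: str, method_b: str, frequency: int):
    """Converged (a, b) threshold pairs at one frequency, pairwise-excluded."""
    sub = df[(df.frequency == frequency) & df.method.isin([method_a, method_b])]
    wide_t = sub.pivot(index=["participant_id", "ear"], columns="method", values="threshold")
    wide_c = sub.pivot(index=["participant_id", "ear"], columns="method", values="converged")
    if method_a not in wide_t or method_b not in wide_t:
        return None
    keep = (
        wide_t[[method_a, method_b]].notna().all(axis=1)
        & wide_c[method_a].astype(bool)
        & wide_c[method_b].astype(bool)
    )
    wide_t = wide_t[keep]
    return wide_t[method_a].to_numpy(), wide_t[method_b].to_numpy()


def summarize_study(
    dataset: StudyDataset,
    tolerance: float = 10.0,
    conf: float = 0.95,
) -> StudySummary:
    """Run the full statistics battery on a study dataset.

    Per frequency: Bland-Altman (index vs reference, and retest vs index
    for the retest frequencies), two-way ICCs, and the Pearson correlation
    between per-pair bias and mean. Across frequencies: aggregated LoAs
    and the pooled within-tolerance fractions. Screening: per-frequency
    and any-of ear-level sensitivity/specificity with exact CIs. False
    positives: per-participant session totals (reference vs first index
    test, both ears), compared by pooled t test.
    """
    df = dataset.to_frame()
    frequencies = sorted(df.frequency.unique())
    retest_freqs = sorted(df[df.method == "index_retest"].frequency.unique())

    agreement: dict[int, BlandAltmanResult] = {}
    agreement_icc: dict[int, ICCResult] = {}
    agreement_pcc: dict[int, PearsonResult] = {}
    trt: dict[int, BlandAltmanResult] = {}
    trt_icc: dict[int, ICCResult] = {}

    all_ref, all_idx = [], []
    all_t1, all_t2 = [], []
    n_excluded = 0

    for f in frequencies:
        pair = _paired(df, "reference", "index", f)
        if pair is None:
            continue
        ref, idx = pair
        n_total_pairs = df[(df.frequency == f) & (df.method == "reference")].shape[0]
        n_excluded += n_total_pairs - ref.size
        if ref.size >= 3:
            agreement[f] = bland_altman(ref, idx, conf=conf)
            agreement_icc[f] = icc_two_way(np.column_stack([ref, idx]), conf=conf)
            agreement_pcc[f] = pearson_r((ref + idx) / 2.0, idx - ref)
            all_ref.append(ref)
            all_idx.append(idx)

    for f in retest_freqs:
        pair = _paired(df, "index", "index_retest", f)
        if pair is None:
            continue
        t1, t2 = pair
        if t1.size >= 3:
            trt[f] = bland_altman(t1, t2, conf=conf)
            trt_icc[f] = icc_two_way(np.column_stack([t1, t2]), conf=conf)
            all_t1.append(t1)
            all_t2.append(t2)

    if len(agreement) < 2:
        raise ValueError("need agreement results at >= 2 frequencies")
    aggregate = aggregate_loa(list(agreement.values()))
    aggregate_trt = aggregate_loa(list(trt.values())) if len(trt) >= 2 else None

    tol = within_tolerance(np.concatenate(all_ref), np.concatenate(all_idx), tolerance)
    tol_trt = (
        within_tolerance(np.concatenate(all_t1), np.concatenate(all_t2), tolerance)
        if all_t1
        else None
    )

    labels = classify_screening(dataset)
    diagnostics_by_frequency = {}
    for f in dataset.screening_frequencies:
        sub = labels.per_frequency[labels.per_frequency.frequency == f]
        if len(sub):
            diagnostics_by_frequency[f] = diagnostic_accuracy(
                sub.truth.to_numpy(), sub.prediction.to_numpy(), conf
            )
    screening = diagnostic_accuracy(
        labels.per_ear.truth.to_numpy(), labels.per_ear.prediction.to_numpy(), conf
    )

    fp_ref = (
        df[df.method == "reference"]
        .groupby("participant_id")["n_false_positives"].sum()
        .astype(int)
    )
    fp_idx = (
        df[df.method == "index"]
        .groupby("participant_id")["n_false_positives"].sum()
        .astype(int)
    )
    fp_test = (
        two_sample_t(fp_ref.to_numpy(), fp_idx.to_numpy())
        if len(fp_ref) >= 2 and len(fp_idx) >= 2
        else None
    )

    n_pairs = sum(r.size for r in all_ref)
    return StudySummary(
        agreement=agreement,
        agreement_icc=agreement_icc,
        agreement_pcc=agreement_pcc,
        trt=trt,
        trt_icc=trt_icc,
        aggregate=aggregate,
        aggregate_trt=aggregate_trt,
        tolerance=tol,
        tolerance_trt=tol_trt,
        diagnostics_by_frequency=diagnostics_by_frequency,
        screening=screening,
        labels=labels,
        fp_test=fp_test,
        fp_reference=fp_ref.tolist(),
        fp_index=fp_idx.tolist(),
        n_pairs=n_pairs,
        n_pairs_excluded=n_excluded,
    )
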