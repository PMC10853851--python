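"""Study harness: replay the plugged-ear validation protocol in silico.

For every ear of every participant the harness runs

* the reference engine (modified Hughson-Westlake) at all six frequencies,
* the index engine (2-down-1-up staircase) at all six frequencies in the
  protocol order 2000, 4000, 8000, 1000, 500, 250 Hz,
* an immediate staircase retest at 2000, 4000, 8000 and 500 Hz,

with the reference-vs-index order randomized per participant, a
conditioning gate before the index session, and an ambient-noise gate
before anything runs. The result is a :class:`StudyDataset` of paired
measurements ready for the agreement-statistics battery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .engines import (
    HWConfig,
    StaircaseConfig,
    TestSessionConfig,
    check_ambient,
    run_conditioning,
    run_hughson_westlake,
    run_staircase,
)
from .listeners import (
    DEFAULT_INDEX_PSYCHOMETRICS,
    DEFAULT_REFERENCE_PSYCHOMETRICS,
    Participant,
    PsychometricParams,
    SimulatedListener,
)

logger = logging.getLogger(__name__)

__all__ = [
    "METHODS",
    "MeasurementRecord",
    "StudyDataset",
    "ScreeningLabels",
    "StudyError",
    "run_study",
    "classify_screening",
]

METHODS = ("reference", "index", "index_retest")

CSV_COLUMNS = [
    "participant_id",
    "ear",
    "plugged",
    "frequency",
    "method",
    "threshold",
    "converged",
    "n_false_positives",
]


class StudyError(RuntimeError):
    """A protocol gate failed or the dataset is unusable."""


@dataclass(frozen=True)
class MeasurementRecord:
    """One threshold measurement: who, which ear, which method, the result."""

    participant_id: str
    ear: str
    plugged: bool
    frequency: int
    method: str
    threshold: float
    converged: bool
    n_false_positives: int

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.ear not in ("left", "right"):
            raise ValueError(f"unknown ear {self.ear!r}")


@dataclass
class StudyDataset:
    """Paired measurements plus the screening rule parameters.

    ``test_orders`` (participant -> 'reference_first' | 'index_first') and
    ``excluded_ears`` are run metadata; they are not part of the CSV schema
    and are not compared for dataset equality.
    """

    records: list[MeasurementRecord]
    screening_frequencies: tuple[int, ...] = (250, 1000, 2000, 4000)
    impairment_criterion: float = 20.0
    test_orders: dict[str, str] = field(default_factory=dict, compare=False)
    excluded_ears: list[tuple[str, str, str]] = field(default_factory=list, compare=False)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(r) for r in self.records], columns=CSV_COLUMNS)
        return df.sort_values(
            ["participant_id", "ear", "frequency", "method"], kind="mergesort"
        ).reset_index(drop=True)

    def write_csv(self, path: str | Path) -> None:
        # %.17g keeps the text round-trip exact for float64 thresholds
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        screening_frequencies: tuple[int, ...] = (250, 1000, 2000, 4000),
        impairment_criterion: float = 20.0,
    ) -> "StudyDataset":
        records = [
            MeasurementRecord(
                participant_id=str(row.participant_id),
                ear=str(row.ear),
                plugged=bool(row.plugged),
                frequency=int(row.frequency),
                method=str(row.method),
                threshold=float(row.threshold),
                converged=bool(row.converged),
                n_false_positives=int(row.n_false_positives),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(records, screening_frequencies, impairment_criterion)

    @classmethod
    def read_csv(cls, path: str | Path, **kwargs) -> "StudyDataset":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls.from_frame(df, **kwargs)


def _run_method(
    method: str,
    listener: SimulatedListener,
    frequencies: Iterable[int],
    participant: Participant,
    ear_name: str,
    staircase: StaircaseConfig,
    hw: HWConfig,
    rng: np.random.Generator,
) -> list[MeasurementRecord]:
    ear = participant.ears[ear_name]
    records = []
    for f in frequencies:
        if method == "reference":
            result = run_hughson_westlake(listener, f, hw, rng)
        else:
            result = run_staircase(listener, f, staircase, rng)
        records.append(
            MeasurementRecord(
                participant_id=participant.participant_id,
                ear=ear_name,
                plugged=ear.plugged,
                frequency=f,
                method=method,
                threshold=result.threshold,
                converged=result.converged,
                n_false_positives=result.n_false_positives,
            )
        )
    return records


def run_study(
    cohort: Sequence[Participant],
    session: TestSessionConfig | None = None,
    staircase: StaircaseConfig | None = None,
    hw: HWConfig | None = None,
    psychometrics_reference: PsychometricParams = DEFAULT_REFERENCE_PSYCHOMETRICS,
    psychometrics_index: PsychometricParams = DEFAULT_INDEX_PSYCHOMETRICS,
    ambient_noise_db: float = 35.0,
    attenuation_jitter_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> StudyDataset:
    """Run the full validation protocol on a simulated cohort.

    Per ear: conditioning gate, then reference and index sessions in a
    per-participant randomized order, then the immediate retest. Ears whose
    conditioning fails are excluded and logged; non-converged engine runs
    are recorded with ``converged=False`` (the statistics layer drops them
    pairwise). ``attenuation_jitter_sd`` adds an optional per-session
    Gaussian perturbation to the plug attenuation, emulating a plug whose
    seal drifts between tests (off by default).
    """
    if not cohort:
        raise StudyError("cohort is empty")
    session = session or TestSessionConfig()
    staircase = staircase or StaircaseConfig()
    hw = hw or HWConfig()
    rng = np.random.default_rng(rng)

    if not check_ambient(ambient_noise_db, session):
        raise StudyError(
            f"ambient noise {ambient_noise_db} dB is not below the "
            f"{session.ambient_limit} dB limit"
        )

    def jittered(ear):
        if not ear.plugged or attenuation_jitter_sd == 0:
            return ear
        att = {
            f: a + rng.normal(0.0, attenuation_jitter_sd)
            for f, a in ear.attenuation.items()
        }
        return type(ear)(ear.true_thresholds, plugged=True, attenuation=att)

    records: list[MeasurementRecord] = []
    test_orders: dict[str, str] = {}
    excluded: list[tuple[str, str, str]] = []

    for participant in cohort:
        reference_first = bool(rng.random() < 0.5)
        test_orders[participant.participant_id] = (
            "reference_first" if reference_first else "index_first"
        )
        for ear_name in ("left", "right"):
            ear = participant.ears[ear_name]
            index_listener = SimulatedListener(jittered(ear), psychometrics_index)
            reference_listener = SimulatedListener(jittered(ear), psychometrics_reference)

            if not run_conditioning(index_listener, session, rng):
                excluded.append(
                    (participant.participant_id, ear_name, "conditioning_failed")
                )
                logger.warning(
                    "excluding %s/%s ear: conditioning failed",
                    participant.participant_id,
                    ear_name,
                )
                continue

            sessions = [
                ("reference", reference_listener, session.frequency_order),
                ("index", index_listener, session.frequency_order),
            ]
            if not reference_first:
                sessions.reverse()
            # retest follows immediately after the index test
            idx = next(i for i, s in enumerate(sessions) if s[0] == "index")
            sessions.insert(
                idx + 1, ("index_retest", index_listener, session.retest_order)
            )
            for method, listener, freqs in sessions:
                records.extend(
                    _run_method(
                        method, listener, freqs, participant, ear_name,
                        staircase, hw, rng,
                    )
                )

    n_nc = sum(not r.converged for r in records)
    if n_nc:
        logger.info("%d of %d runs flagged not-converged", n_nc, len(records))

    return StudyDataset(
        records=records,
        test_orders=test_orders,
        excluded_ears=excluded,
    )


@dataclass
class ScreeningLabels:
    """Truth/prediction labels for the >criterion screening classification.

    ``per_frequency`` has one row per (participant, ear, screening
    frequency) with boolean ``truth`` (reference threshold > criterion) and
    ``prediction`` (index threshold > criterion). ``per_ear`` applies the
    any-frequency rule: an ear is positive iff any screening frequency
    exceeds the criterion.
    """

    per_frequency: pd.DataFrame
    per_ear: pd.DataFrame
    criterion: float
    screening_frequencies: tuple[int, ...]


def classify_screening(dataset: StudyDataset) -> ScreeningLabels:
    """Build screening labels from the paired reference/index records.

    Raises :class:`StudyError` naming the (participant, ear, frequency) if
    a screening-frequency record is missing. Pairs in which either run
    failed to converge are dropped (pairwise exclusion); an ear with no
    usable screening pair at all is dropped from the ear-level table.
    """
    df = dataset.to_frame()
    crit = dataset.impairment_criterion
    rows = []
    ears = df[["participant_id", "ear"]].drop_duplicates().itertuples(index=False)
    for participant_id, ear in ears:
        for f in dataset.screening_frequencies:
            sub = df[
                (df.participant_id == participant_id)
                & (df.ear == ear)
                & (df.frequency == f)
            ]
            pair = {}
            for method in ("reference", "index"):
                rec = sub[sub.method == method]
                if rec.empty:
                    raise StudyError(
                        f"missing {method} record for ({participant_id}, {ear}, {f} Hz)"
                    )
                pair[method] = rec.iloc[0]
            if not (pair["reference"].converged and pair["index"].converged):
                continue
            rows.append(
                {
                    "participant_id": participant_id,
                    "ear": ear,
                    "frequency": f,
                    "truth": bool(pair["reference"].threshold > crit),
                    "prediction": bool(pair["index"].threshold > crit),
                }
            )
    per_frequency = pd.DataFrame(
        rows, columns=["participant_id", "ear", "frequency", "truth", "prediction"]
    )
    per_ear = (
        per_frequency.groupby(["participant_id", "ear"], as_index=False)[
            ["truth", "prediction"]
        ].any()
        if len(per_frequency)
        else pd.DataFrame(columns=["participant_id", "ear", "truth", "prediction"])
    )
    return ScreeningLabels(
        per_frequency=per_frequency,
        per_ear=per_ear,
        criterion=crit,
        screening_frequencies=dataset.screening_frequencies,
    )
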