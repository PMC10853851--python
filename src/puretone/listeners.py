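"""Synthetic listeners: psychometric response model and cohort generation.

A simulated listener detects a tone with probability

    P(response | level) = (1 - lapse) * Phi((level - theta) / sigma)

where ``theta`` is the effective threshold of the tested ear (true threshold
plus earplug attenuation when plugged), ``sigma`` sets the psychometric
slope (``sigma = 0`` gives the ideal step-function listener used in
hand-traceable tests) and ``lapse`` is the rate of missed suprathreshold
tones. Independently, each presentation carries a per-trial probability
``fp_rate`` of a pre-onset tap — a false positive, which the engines log
and re-present.

Cohorts emulate a plugged-ear validation study: healthy-adult true
thresholds drawn from a truncated normal, the left ear fitted with a foam
earplug whose frequency-dependent attenuation creates a conductive loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_FREQUENCIES",
    "DEFAULT_ATTENUATION",
    "DEFAULT_REFERENCE_PSYCHOMETRICS",
    "DEFAULT_INDEX_PSYCHOMETRICS",
    "PsychometricParams",
    "EarProfile",
    "Participant",
    "CohortConfig",
    "response_probability",
    "simulate_trial",
    "generate_cohort",
    "SimulatedListener",
    "DeterministicListener",
    "cohort_to_frame",
    "write_cohort_csv",
]

DEFAULT_FREQUENCIES: tuple[int, ...] = (250, 500, 1000, 2000, 4000, 8000)

#: Foam-earplug attenuation by frequency (dB); rises with frequency, as foam
#: plugs do, and exceeds the 20 dB screening criterion everywhere so plugged
#: ears are unambiguous screening positives. Synthetic defaults, configurable.
DEFAULT_ATTENUATION: dict[int, float] = {
    250: 25.0,
    500: 28.0,
    1000: 30.0,
    2000: 33.0,
    4000: 38.0,
    8000: 40.0,
}


@dataclass(frozen=True)
class PsychometricParams:
    """Response-model parameters: slope spread (dB), lapse and FP probabilities."""

    slope_sigma: float = 4.0
    lapse_rate: float = 0.02
    fp_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.slope_sigma < 0:
            raise ValueError("slope_sigma must be >= 0")
        if not 0 <= self.lapse_rate <= 1:
            raise ValueError("lapse_rate must be in [0, 1]")
        if not 0 <= self.fp_rate <= 1:
            raise ValueError("fp_rate must be in [0, 1]")


#: Defaults used when emulating the two test sessions: the tap-to-respond
#: staircase session draws more spurious taps than the hand-responder
#: reference session.
DEFAULT_REFERENCE_PSYCHOMETRICS = PsychometricParams(4.0, 0.02, 0.05)
DEFAULT_INDEX_PSYCHOMETRICS = PsychometricParams(4.0, 0.02, 0.10)


@dataclass(frozen=True)
class EarProfile:
    """One ear: per-frequency true thresholds, plug state, plug attenuation."""

    true_thresholds: Mapping[int, float]
    plugged: bool = False
    attenuation: Mapping[int, float] = field(default_factory=dict)

    def effective_threshold(self, frequency: int) -> float:
        """True threshold plus plug attenuation (if plugged) at ``frequency``."""
        base = self.true_thresholds[frequency]
        if self.plugged:
            return base + self.attenuation[frequency]
        return base


@dataclass(frozen=True)
class Participant:
    """A study participant: left ear plugged, right ear open."""

    participant_id: str
    left: EarProfile
    right: EarProfile

    @property
    def ears(self) -> dict[str, EarProfile]:
        return {"left": self.left, "right": self.right}


@dataclass(frozen=True)
class CohortConfig:
    """Cohort generator settings.

    Defaults describe healthy adults with no history of hearing impairment:
    per-frequency true thresholds ~ Normal(5, 5) dB HL truncated to
    [-10, 20], 30 participants, left ear plugged with
    :data:`DEFAULT_ATTENUATION`.
    """

    n_participants: int = 30
    threshold_mean: float = 5.0
    threshold_sd: float = 5.0
    threshold_bounds: tuple[float, float] = (-10.0, 20.0)
    frequencies: tuple[int, ...] = DEFAULT_FREQUENCIES
    attenuation_profile: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_ATTENUATION)
    )
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if len(self.frequencies) == 0:
            raise ValueError("frequency set must be non-empty")
        lo, hi = self.threshold_bounds
        if not lo < hi:
            raise ValueError("threshold_bounds must be ordered (lo < hi)")
        if self.threshold_sd < 0:
            raise ValueError("threshold_sd must be >= 0")
        missing = set(self.frequencies) - set(self.attenuation_profile)
        if missing:
            raise ValueError(f"attenuation_profile missing frequencies: {sorted(missing)}")


_SQRT2 = math.sqrt(2.0)


def response_probability(
    params: PsychometricParams, level: float, effective_threshold: float
) -> float:
    """Detection probability (1 - lapse) * Phi((level - theta) / sigma).

    With ``slope_sigma == 0`` this degenerates to the step function
    ``(1 - lapse) * [level >= theta]``.
    """
    if params.slope_sigma == 0:
        detect = 1.0 if level >= effective_threshold else 0.0
    else:
        z = (level - effective_threshold) / params.slope_sigma
        detect = 0.5 * (1.0 + math.erf(z / _SQRT2))
    return (1.0 - params.lapse_rate) * detect


def simulate_trial(
    params: PsychometricParams,
    level: float,
    effective_threshold: float,
    rng: np.random.Generator,
) -> tuple[bool, bool]:
    """Draw one trial outcome: ``(responded, false_positive)``.

    The pre-onset false-positive draw comes first; a false positive
    pre-empts the detection draw (the tone stops at the tap, so the
    presentation never completes).
    """
    if rng.random() < params.fp_rate:
        return False, True
    p = response_probability(params, level, effective_threshold)
    if p <= 0.0:
        return False, False
    if p >= 1.0:
        return True, False
    return bool(rng.random() < p), False


class SimulatedListener:
    """Responder adapter binding an :class:`EarProfile` to psychometric params."""

    def __init__(self, ear: EarProfile, params: PsychometricParams) -> None:
        self.ear = ear
        self.params = params

    def respond(
        self, frequency: int, level: float, rng: np.random.Generator
    ) -> tuple[bool, bool]:
        return simulate_trial(
            self.params, level, self.ear.effective_threshold(frequency), rng
        )


class DeterministicListener:
    """Ideal step-function listener: hears iff level >= threshold.

    ``threshold`` may be a scalar (flat audiogram) or a per-frequency map.
    No lapses, no false positives — the workhorse of hand-traceable tests.
    """

    def __init__(self, threshold: float | Mapping[int, float]) -> None:
        self.threshold = threshold

    def _threshold_at(self, frequency: int) -> float:
        if isinstance(self.threshold, Mapping):
            return self.threshold[frequency]
        return float(self.threshold)

    def respond(
        self, frequency: int, level: float, rng: np.random.Generator
    ) -> tuple[bool, bool]:
        return level >= self._threshold_at(frequency), False


def _draw_thresholds(
    config: CohortConfig, rng: np.random.Generator
) -> dict[int, float]:
    lo, hi = config.threshold_bounds
    out: dict[int, float] = {}
    for f in config.frequencies:
        if config.threshold_sd == 0:
            val = config.threshold_mean
            if not lo <= val <= hi:
                raise ValueError("threshold_mean outside threshold_bounds with sd=0")
        else:
            # rejection sampling keeps the draw order simple and reproducible
            while True:
                val = rng.normal(config.threshold_mean, config.threshold_sd)
                if lo <= val <= hi:
                    break
        out[f] = float(val)
    return out


def generate_cohort(
    config: CohortConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> list[Participant]:
    """Generate the simulated cohort: ``n_participants``, left ears plugged.

    True thresholds are drawn per ear and frequency from
    Normal(threshold_mean, threshold_sd) truncated to ``threshold_bounds``.
    Reproducible: the same config and seed give the same cohort.
    """
    config = config or CohortConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    else:
        rng = np.random.default_rng(rng)
    attenuation = dict(config.attenuation_profile)
    cohort: list[Participant] = []
    for i in range(config.n_participants):
        left = EarProfile(_draw_thresholds(config, rng), plugged=True, attenuation=attenuation)
        right = EarProfile(_draw_thresholds(config, rng), plugged=False, attenuation=attenuation)
        cohort.append(Participant(f"P{i + 1:02d}", left=left, right=right))
    return cohort


def cohort_to_frame(cohort: Sequence[Participant]) -> pd.DataFrame:
    """Long-format cohort table (one row per participant, ear, frequency)."""
    rows = []
    for p in cohort:
        for ear_name, ear in p.ears.items():
            for f in sorted(ear.true_thresholds):
                rows.append(
                    {
                        "participant_id": p.participant_id,
                        "ear": ear_name,
                        "frequency_hz": f,
                        "true_threshold_db": ear.true_thresholds[f],
                        "effective_threshold_db": ear.effective_threshold(f),
                        "plugged": ear.plugged,
                    }
                )
    return pd.DataFrame(rows)


def write_cohort_csv(cohort: Sequence[Participant], path: str | Path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)
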