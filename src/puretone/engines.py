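"""Automated pure-tone threshold engines.

Two deterministic state machines drive a listener (anything satisfying the
:class:`Responder` contract) to an air-conduction threshold estimate:

* :func:`run_staircase` — an adaptive transformed staircase (2-down-1-up,
  10 dB down / 5 dB up from 60 dB HL, stopping after 5 reversals; the
  threshold is the mean of the final 3 reversal levels).
* :func:`run_hughson_westlake` — the modified Hughson-Westlake clinical
  procedure (descend 10 dB per response, ascend in 5 dB steps after a miss;
  the threshold is the lowest level with 2 ascending confirmations out of
  up to 3 ascents).

Both engines log every presentation, count false-positive taps (a tap in
the randomized 0-3 s pre-onset window), and flag non-convergence instead of
raising, so a study harness can account for every run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence

import numpy as np

__all__ = [
    "ToneStimulus",
    "TrialRecord",
    "StaircaseConfig",
    "HWConfig",
    "TestSessionConfig",
    "ThresholdResult",
    "Responder",
    "run_staircase",
    "run_hughson_westlake",
    "run_conditioning",
    "check_ambient",
]


class Responder(Protocol):
    """Anything that can answer a heard / not-heard query for a tone.

    ``respond`` returns ``(responded, false_positive)``; a false positive
    means the listener tapped during the pre-onset window, before the tone
    started, and therefore did not hear this presentation.
    """

    def respond(
        self, frequency: int, level: float, rng: np.random.Generator
    ) -> tuple[bool, bool]: ...


@dataclass(frozen=True)
class ToneStimulus:
    """One tone presentation: frequency (Hz), level (dB HL), onset delay (s)."""

    frequency: int
    level: float
    onset_delay: float

    def __post_init__(self) -> None:
        if self.onset_delay < 0:
            raise ValueError("onset_delay must be >= 0")


@dataclass(frozen=True)
class TrialRecord:
    """One logged presentation and its outcome.

    ``level_change_after`` is the signed dB step the engine applied after
    this trial, or ``None`` when the trial left the level unchanged (a
    false positive is re-presented; a partial hit waits for confirmation;
    the final trial of a run has no successor).
    """

    stimulus: ToneStimulus
    responded: bool
    false_positive: bool
    level_change_after: Optional[float]


def _check_bounds(floor: float, start: float, ceiling: float) -> None:
    if not floor < start < ceiling:
        raise ValueError(
            f"require level_floor < start_level < level_ceiling, "
            f"got {floor} / {start} / {ceiling}"
        )


@dataclass(frozen=True)
class StaircaseConfig:
    """Parameters of the 2-down-1-up adaptive staircase.

    Defaults encode the published procedure: start 60 dB HL, 10 dB down
    after 2 consecutive hits, 5 dB up after each miss, stop at 5 reversals
    and average the final 3 reversal levels.
    """

    start_level: float = 60.0
    step_down: float = 10.0
    step_up: float = 5.0
    down_rule: int = 2
    up_rule: int = 1
    reversals_required: int = 5
    reversals_averaged: int = 3
    level_floor: float = -10.0
    level_ceiling: float = 100.0
    max_trials: int = 80

    def __post_init__(self) -> None:
        if self.step_down <= 0 or self.step_up <= 0:
            raise ValueError("step sizes must be > 0")
        if self.down_rule < 1 or self.up_rule < 1:
            raise ValueError("down_rule and up_rule must be >= 1")
        if self.reversals_averaged > self.reversals_required:
            raise ValueError("reversals_averaged must be <= reversals_required")
        if self.reversals_averaged < 1:
            raise ValueError("reversals_averaged must be >= 1")
        _check_bounds(self.level_floor, self.start_level, self.level_ceiling)
        if self.max_trials < 1:
            raise ValueError("max_trials must be >= 1")


@dataclass(frozen=True)
class HWConfig:
    """Parameters of the modified Hughson-Westlake procedure.

    The threshold criterion is ``confirmations_required`` responses on
    ascending presentations at a level, out of at most
    ``presentations_per_level`` ascents considered at that level.
    """

    start_level: float = 60.0
    step_down: float = 10.0
    step_up: float = 5.0
    confirmations_required: int = 2
    presentations_per_level: int = 3
    level_floor: float = -10.0
    level_ceiling: float = 100.0
    max_trials: int = 80

    def __post_init__(self) -> None:
        if self.step_down <= 0 or self.step_up <= 0:
            raise ValueError("step sizes must be > 0")
        if self.confirmations_required > self.presentations_per_level:
            raise ValueError(
                "confirmations_required must be <= presentations_per_level"
            )
        if self.confirmations_required < 1:
            raise ValueError("confirmations_required must be >= 1")
        _check_bounds(self.level_floor, self.start_level, self.level_ceiling)
        if self.max_trials < 1:
            raise ValueError("max_trials must be >= 1")


@dataclass(frozen=True)
class TestSessionConfig:
    """Session-level protocol: frequency orders, conditioning, ambient gate."""

    __test__ = False  # dataclass, not a pytest collection target

    frequency_order: tuple[int, ...] = (2000, 4000, 8000, 1000, 500, 250)
    retest_order: tuple[int, ...] = (2000, 4000, 8000, 500)
    conditioning_frequency: int = 1000
    conditioning_level: float = 60.0
    conditioning_attempts: int = 3
    ambient_limit: float = 40.0

    def __post_init__(self) -> None:
        if not set(self.retest_order) <= set(self.frequency_order):
            raise ValueError("retest_order must be a subset of frequency_order")
        if self.ambient_limit <= 0:
            raise ValueError("ambient_limit must be > 0")
        if self.conditioning_attempts < 1:
            raise ValueError("conditioning_attempts must be >= 1")


@dataclass
class ThresholdResult:
    """Outcome of one engine run at one frequency.

    ``converged`` is False when the run hit the trial cap or pinned at a
    level bound; ``threshold`` is then a provisional value (the bound, or
    the mean of whatever reversal tail exists) and the run should be
    excluded from agreement statistics.
    """

    frequency: int
    threshold: float
    converged: bool
    reversal_levels: list[float]
    trials: list[TrialRecord]
    n_false_positives: int
    engine: str

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def _clip(level: float, floor: float, ceiling: float) -> float:
    return min(max(level, floor), ceiling)


def run_staircase(
    listener: Responder,
    frequency: int,
    config: StaircaseConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> ThresholdResult:
    """Run the 2-down-1-up staircase at one frequency.

    The level drops ``step_down`` after ``down_rule`` consecutive hits and
    rises ``step_up`` after ``up_rule`` consecutive misses. A reversal is
    recorded whenever a level-change decision has the opposite sign to the
    previous one; its level is the level of the trial that triggered the
    change (standard Levitt bookkeeping). After ``reversals_required``
    reversals the threshold is the mean of the last ``reversals_averaged``
    reversal levels.

    False-positive taps (pre-onset) are logged and the presentation is
    repeated at the same level without touching the staircase state, so a
    trigger-happy listener inflates the FP count but not the track.

    Non-convergence — the trial cap, or two consecutive level-change
    decisions clamped at a bound (a pinned track) — is flagged on the
    result, never raised.
    """
    config = config or StaircaseConfig()
    rng = np.random.default_rng(rng)

    level = config.start_level
    hits = 0
    misses = 0
    prev_direction = 0
    pinned = 0
    reversals: list[float] = []
    trials: list[TrialRecord] = []
    n_fp = 0
    converged = False
    pinned_at: float | None = None

    while len(trials) < config.max_trials:
        stim = ToneStimulus(frequency, level, rng.uniform(0.0, 3.0))
        responded, fp = listener.respond(frequency, level, rng)
        if fp:
            n_fp += 1
            trials.append(TrialRecord(stim, False, True, None))
            continue
        if responded:
            hits += 1
            misses = 0
            if hits < config.down_rule:
                trials.append(TrialRecord(stim, True, False, None))
                continue
            hits = 0
            change = -config.step_down
        else:
            misses += 1
            hits = 0
            if misses < config.up_rule:
                trials.append(TrialRecord(stim, False, False, None))
                continue
            misses = 0
            change = config.step_up

        direction = 1 if change > 0 else -1
        if prev_direction != 0 and direction != prev_direction:
            reversals.append(level)
        prev_direction = direction

        new_level = _clip(level + change, config.level_floor, config.level_ceiling)
        trials.append(TrialRecord(stim, responded, False, new_level - level))

        if len(reversals) >= config.reversals_required:
            converged = True
            break
        if new_level == level:  # decision clamped at a bound
            pinned += 1
            if pinned >= 2:
                pinned_at = level
                break
        else:
            pinned = 0
        level = new_level

    if converged:
        tail = reversals[-config.reversals_averaged :]
        threshold = float(np.mean(tail))
    elif pinned_at is not None:
        threshold = pinned_at
    elif reversals:
        threshold = float(np.mean(reversals[-config.reversals_averaged :]))
    else:
        threshold = level

    return ThresholdResult(
        frequency=frequency,
        threshold=threshold,
        converged=converged,
        reversal_levels=reversals,
        trials=trials,
        n_false_positives=n_fp,
        engine="staircase",
    )


def run_hughson_westlake(
    listener: Responder,
    frequency: int,
    config: HWConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> ThresholdResult:
    """Run the modified Hughson-Westlake procedure at one frequency.

    Dialect: descend ``step_down`` after every response until the first
    miss; then ascend in ``step_up`` steps until a response. Every
    presentation in the ascending phase counts as an ascent at its level;
    a response there is one confirmation, after which the level drops
    ``step_down`` and re-ascends. The threshold is the lowest level
    accumulating ``confirmations_required`` confirmations within the first
    ``presentations_per_level`` ascents at that level. A level that burns
    its ascent budget without confirming is disqualified.

    ``reversal_levels`` on the result stays empty — the procedure has no
    reversal bookkeeping.
    """
    config = config or HWConfig()
    rng = np.random.default_rng(rng)

    level = config.start_level
    ascending = False
    pinned = 0
    trials: list[TrialRecord] = []
    n_fp = 0
    ascent_presentations: dict[float, int] = {}
    ascent_confirmations: dict[float, int] = {}
    converged = False
    threshold: float | None = None
    pinned_at: float | None = None

    while len(trials) < config.max_trials:
        stim = ToneStimulus(frequency, level, rng.uniform(0.0, 3.0))
        responded, fp = listener.respond(frequency, level, rng)
        if fp:
            n_fp += 1
            trials.append(TrialRecord(stim, False, True, None))
            continue

        if not ascending:
            if responded:
                change = -config.step_down
            else:
                ascending = True
                change = config.step_up
        else:
            ascent_presentations[level] = ascent_presentations.get(level, 0) + 1
            if responded:
                ascent_confirmations[level] = ascent_confirmations.get(level, 0) + 1
                eligible = (
                    ascent_presentations[level] <= config.presentations_per_level
                )
                if (
                    eligible
                    and ascent_confirmations[level] >= config.confirmations_required
                ):
                    threshold = level
                    converged = True
                    trials.append(TrialRecord(stim, True, False, None))
                    break
                change = -config.step_down
            else:
                change = config.step_up

        new_level = _clip(level + change, config.level_floor, config.level_ceiling)
        trials.append(TrialRecord(stim, responded, False, new_level - level))
        if new_level == level:
            pinned += 1
            if pinned >= 2:
                pinned_at = level
                break
        else:
            pinned = 0
        level = new_level

    if not converged:
        threshold = pinned_at if pinned_at is not None else level

    return ThresholdResult(
        frequency=frequency,
        threshold=float(threshold),
        converged=converged,
        reversal_levels=[],
        trials=trials,
        n_false_positives=n_fp,
        engine="hughson_westlake",
    )


def run_conditioning(
    listener: Responder,
    config: TestSessionConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> bool:
    """Conditioning gate: the listener must tap to a suprathreshold tone.

    Up to ``conditioning_attempts`` attempts at ``conditioning_level``
    dB HL, ``conditioning_frequency`` Hz; a genuine response on any
    attempt passes. As in the engines, a pre-onset tap repeats the
    presentation without consuming an attempt (capped at 5 presentations
    per attempt, so an always-tapping listener still fails). Failure means
    the session must not proceed.
    """
    config = config or TestSessionConfig()
    rng = np.random.default_rng(rng)
    for _ in range(config.conditioning_attempts):
        for _ in range(5):  # FP re-presentation cap per attempt
            responded, fp = listener.respond(
                config.conditioning_frequency, config.conditioning_level, rng
            )
            if not fp:
                break
        if responded and not fp:
            return True
    return False


def check_ambient(noise_level: float, config: TestSessionConfig | None = None) -> bool:
    """Ambient-noise gate: pass iff the measured level is strictly below the limit."""
    config = config or TestSessionConfig()
    if noise_level < 0:
        raise ValueError("noise_level must be >= 0")
    return noise_level < config.ambient_limit
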