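"""Independent oracles used by the test suite.

These deliberately re-derive expected values by a different route than the
library (post-hoc decision-list bookkeeping for the staircase, a
closed-form grid rule for the ascending procedure, explicit-loop ANOVA
sums of squares for the ICC) so that agreement is a genuine cross-check.
"""

from __future__ import annotations

import math


def trace_staircase(
    hears,
    start: float = 60.0,
    step_down: float = 10.0,
    step_up: float = 5.0,
    down_rule: int = 2,
    reversals_required: int = 5,
    reversals_averaged: int = 3,
    floor: float = -10.0,
    ceiling: float = 100.0,
    max_trials: int = 80,
):
    """Step-by-step trace of a 2-down-1-up track for a deterministic listener.

    Keeps a flat list of (level, direction) decisions and recomputes the
    reversal list from scratch after every trial, instead of the library's
    online bookkeeping. Returns (reversal_levels, threshold, n_trials) or
    None if the track does not converge.
    """
    level = start
    hits = 0
    trials = 0
    decisions: list[tuple[float, int]] = []
    while trials < max_trials:
        trials += 1
        if hears(level):
            hits += 1
            if hits < down_rule:
                continue
            hits = 0
            decisions.append((level, -1))
            level = max(level - step_down, floor)
        else:
            hits = 0
            decisions.append((level, +1))
            level = min(level + step_up, ceiling)
        revs = [
            lvl
            for i, (lvl, sign) in enumerate(decisions)
            if i > 0 and sign != decisions[i - 1][1]
        ]
        if len(revs) >= reversals_required:
            revs = revs[:reversals_required]
            tail = revs[-reversals_averaged:]
            return revs, sum(tail) / len(tail), trials
    return None


def hw_grid_threshold(true_threshold: float, step_up: float = 5.0) -> float:
    """Ascending-procedure result for an ideal step listener.

    The smallest level on the 5-dB ascent grid at or above the true
    threshold (grid anchored at 0 because the start level and both step
    sizes are multiples of 5).
    """
    return step_up * math.ceil(true_threshold / step_up)


def icc_oracle(matrix) -> tuple[float, float]:
    """ICC(A,1) and ICC(C,1) via explicit-loop ANOVA sums of squares."""
    n = len(matrix)
    k = len(matrix[0])
    grand = sum(sum(row) for row in matrix) / (n * k)
    row_means = [sum(row) / k for row in matrix]
    col_means = [sum(matrix[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_total = sum((matrix[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    icc_c = (msr - mse) / (msr + (k - 1) * mse)
    icc_a = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    return icc_a, icc_c
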