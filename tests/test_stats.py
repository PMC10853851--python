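"""Agreement/diagnostic statistics against arithmetic and ANOVA oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra.numpy import arrays

from puretone import (
    BlandAltmanResult,
    aggregate_loa,
    bland_altman,
    clopper_pearson,
    diagnostic_accuracy,
    icc_two_way,
    pearson_r,
    two_sample_t,
    two_sample_t_from_stats,
    within_tolerance,
)
from oracles import icc_oracle

# Published per-frequency limits of agreement used as aggregation inputs
# (method-comparison block, then the test-retest block).
COMPARISON_LLOA = [-13.75, -19.62, -19.01, -17.18, -16.19, -16.51]
COMPARISON_ULOA = [17.18, 16.52, 19.47, 22.05, 21.42, 25.71]
TRT_LLOA = [-15.90, -13.84, -10.74, -15.48]
TRT_ULOA = [16.42, 16.64, 12.53, 17.44]


def _ba_from_loa(lloa, uloa):
    return BlandAltmanResult(
        n=60, bias=(lloa + uloa) / 2, sd_diff=(uloa - lloa) / (2 * 1.96),
        lloa=lloa, uloa=uloa, bias_ci=(0, 0), lloa_ci=(0, 0), uloa_ci=(0, 0),
    )


# ---------------------------------------------------------------------------
# Bland-Altman

def test_bland_altman_identical_columns():
    a = np.array([1.0, 5.0, 9.0, 13.0])
    res = bland_altman(a, a)
    assert res.bias == 0 and res.lloa == 0 and res.uloa == 0
    assert res.bias_ci == (0, 0) and res.lloa_ci == (0, 0)


def test_bland_altman_simple_arithmetic():
    res = bland_altman([0.0, 0.0, 0.0], [-5.0, 0.0, 5.0])
    assert res.bias == pytest.approx(0.0)
    assert res.sd_diff == pytest.approx(5.0)
    assert res.lloa == pytest.approx(-9.8)
    assert res.uloa == pytest.approx(9.8)


def test_bland_altman_reproduces_printed_ci_widths():
    """n=60 differences with mean 1.72 and SD (17.18-1.72)/1.96 reproduce
    the published 250 Hz row: bias CI (-0.32, 3.76), LLoA CI about
    (-17.25, -10.25)."""
    sd = (17.18 - 1.72) / 1.96
    z = np.arange(60, dtype=float)
    z = (z - z.mean()) / z.std(ddof=1)
    d = 1.72 + sd * z
    res = bland_altman(np.zeros(60), d)
    assert res.bias == pytest.approx(1.72, abs=1e-9)
    assert res.sd_diff == pytest.approx(sd, abs=1e-9)
    assert res.bias_ci[0] == pytest.approx(-0.32, abs=0.005)
    assert res.bias_ci[1] == pytest.approx(3.76, abs=0.005)
    # printed row rounds to -13.75; the implied value is 1.72 - 15.46 = -13.74
    assert res.lloa == pytest.approx(-13.75, abs=0.015)
    assert res.lloa_ci[0] == pytest.approx(-17.25, abs=0.05)
    assert res.lloa_ci[1] == pytest.approx(-10.25, abs=0.05)


@given(
    arrays(np.float64, st.integers(3, 30), elements=st.floats(-100, 100)),
    arrays(np.float64, st.integers(3, 30), elements=st.floats(-100, 100)),
)
def test_bland_altman_symmetry(a, b):
    n = min(a.size, b.size)
    res = bland_altman(a[:n], b[:n])
    assert res.lloa + res.uloa == pytest.approx(2 * res.bias, abs=1e-9)


def test_bland_altman_input_validation():
    with pytest.raises(ValueError):
        bland_altman([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        bland_altman([1.0, 2.0, np.nan], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# LoA aggregation

def test_aggregate_loa_published_comparison_block():
    agg = aggregate_loa([_ba_from_loa(l, u) for l, u in zip(COMPARISON_LLOA, COMPARISON_ULOA)])
    assert agg.mean_lloa == pytest.approx(-17.04, abs=0.005)
    assert agg.sd_lloa == pytest.approx(2.12, abs=0.005)
    assert agg.mean_uloa == pytest.approx(20.39, abs=0.005)
    assert agg.sd_uloa == pytest.approx(3.41, abs=0.005)


def test_aggregate_loa_published_trt_block():
    agg = aggregate_loa([_ba_from_loa(l, u) for l, u in zip(TRT_LLOA, TRT_ULOA)])
    assert agg.mean_lloa == pytest.approx(-13.99, abs=0.005)
    assert agg.sd_lloa == pytest.approx(2.34, abs=0.005)
    assert agg.mean_uloa == pytest.approx(15.76, abs=0.005)
    assert agg.sd_uloa == pytest.approx(2.20, abs=0.005)


def test_aggregate_loa_identical_inputs():
    agg = aggregate_loa([_ba_from_loa(-10.0, 10.0)] * 3)
    assert agg.sd_lloa == 0 and agg.sd_uloa == 0


# ---------------------------------------------------------------------------
# ICC

def test_icc_identical_columns_degenerate_and_perfect():
    a = np.array([[1.0, 1.0], [5.0, 5.0], [9.0, 9.0], [2.0, 2.0]])
    res = icc_two_way(a)
    assert res.icc_agreement == pytest.approx(1.0)
    assert res.icc_consistency == pytest.approx(1.0)
    flat = icc_two_way(np.full((4, 2), 3.0))
    assert flat.degenerate
    assert flat.icc_agreement == 1.0 and flat.agreement_ci == (1.0, 1.0)


def test_icc_constant_offset_consistency_vs_agreement():
    a = np.array([1.0, 4.0, 7.0, 10.0])
    m = np.column_stack([a, a + 5.0])
    res = icc_two_way(m)
    assert res.icc_consistency == pytest.approx(1.0)
    assert res.icc_agreement < 1.0


def test_icc_fixed_matrix_matches_anova_oracle():
    m = [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0], [7.0, 8.0]]
    res = icc_two_way(m)
    icc_a, icc_c = icc_oracle(m)
    assert res.icc_agreement == pytest.approx(icc_a, abs=1e-12)
    assert res.icc_consistency == pytest.approx(icc_c, abs=1e-12)


@given(st.integers(3, 10), st.integers(0, 10_000))
def test_icc_matches_bruteforce_anova_on_random_matrices(n, seed):
    rng = np.random.default_rng(seed)
    m = rng.normal(10, 5, (n, 2)) + rng.normal(0, 2, (n, 2))
    res = icc_two_way(m)
    icc_a, icc_c = icc_oracle(m.tolist())
    assert res.icc_agreement == pytest.approx(icc_a, rel=1e-9, abs=1e-9)
    assert res.icc_consistency == pytest.approx(icc_c, rel=1e-9, abs=1e-9)
    assert res.icc_agreement <= 1.0 and res.icc_consistency <= 1.0


def test_icc_cross_checked_against_pingouin():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(11)
    for _ in range(3):
        n = int(rng.integers(5, 12))
        m = rng.normal(20, 8, (n, 2))
        m[:, 1] += rng.normal(1, 3, n)
        long = pd.DataFrame(
            {"s": np.repeat(np.arange(n), 2), "r": np.tile([0, 1], n), "y": m.ravel()}
        )
        table = pg.intraclass_corr(long, "s", "r", "y").set_index("Type")
        res = icc_two_way(m)
        assert res.icc_agreement == pytest.approx(table.loc["ICC(A,1)", "ICC"], abs=1e-9)
        assert res.icc_consistency == pytest.approx(table.loc["ICC(C,1)", "ICC"], abs=1e-9)
        lo, hi = table.loc["ICC(A,1)", "CI95"]
        assert res.agreement_ci[0] == pytest.approx(lo, abs=0.01)
        assert res.agreement_ci[1] == pytest.approx(hi, abs=0.01)


# ---------------------------------------------------------------------------
# Pearson

def test_pearson_exact_cases():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    assert pearson_r(x, 2 * x + 1).r == pytest.approx(1.0)
    assert pearson_r([-1.0, 0.0, 1.0], [1.0, -2.0, 1.0]).r == pytest.approx(0.0, abs=1e-12)
    assert pearson_r(x, [1.0, 3.0, 2.0, 4.0]).r == pytest.approx(0.8)


def test_pearson_zero_variance_flagged():
    res = pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    assert not res.defined and np.isnan(res.r)


@given(
    st.floats(0.1, 10), st.floats(-50, 50),
    st.integers(0, 1000),
)
def test_pearson_affine_invariance(scale, shift, seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, 10)
    y = rng.normal(0, 1, 10)
    r0 = pearson_r(x, y).r
    r1 = pearson_r(scale * x + shift, y).r
    assert r1 == pytest.approx(r0, abs=1e-9)


# ---------------------------------------------------------------------------
# tolerance proportion

def test_within_tolerance_boundary_inclusive():
    assert within_tolerance([0.0] * 3, [0.0] * 3).proportion == 1.0
    res = within_tolerance([0.0, 0.0, 0.0], [0.0, 10.0, 11.0])
    assert res.n_within == 2 and res.proportion == pytest.approx(2 / 3)
    assert within_tolerance([0.0] * 4, [15.0, -15.0, 15.0, -15.0]).proportion == 0.0


# ---------------------------------------------------------------------------
# Clopper-Pearson and diagnostic accuracy

@pytest.mark.parametrize(
    "x,n,lo,hi",
    [
        (19, 20, 75.13, 99.87),
        (27, 27, 87.23, 100.00),
        (25, 25, 86.28, 100.00),
        (24, 33, 54.48, 86.70),
        (0, 5, 0.00, 52.18),
    ],
)
def test_clopper_pearson_published_values(x, n, lo, hi):
    got_lo, got_hi = clopper_pearson(x, n)
    assert got_lo == pytest.approx(lo, abs=0.005)
    assert got_hi == pytest.approx(hi, abs=0.005)


def test_clopper_pearson_validation():
    with pytest.raises(ValueError):
        clopper_pearson(5, 4)
    with pytest.raises(ValueError):
        clopper_pearson(-1, 4)
    with pytest.raises(ValueError):
        clopper_pearson(1, 0)


@given(st.integers(0, 30))
def test_clopper_pearson_contains_point_estimate(x):
    lo, hi = clopper_pearson(x, 30)
    p = 100 * x / 30
    assert lo <= p <= hi


def test_diagnostic_accuracy_published_confusion():
    truth = [True] * 27 + [False] * 33
    pred = [True] * 27 + [True] * 9 + [False] * 24
    res = diagnostic_accuracy(truth, pred)
    assert (res.tp, res.fn, res.tn, res.fp) == (27, 0, 24, 9)
    assert res.sensitivity == pytest.approx(100.0)
    assert res.specificity == pytest.approx(72.73, abs=0.005)
    assert res.sensitivity_ci[0] == pytest.approx(87.23, abs=0.005)
    assert res.specificity_ci == (pytest.approx(54.48, abs=0.005), pytest.approx(86.70, abs=0.005))


def test_diagnostic_accuracy_perfect_and_partial():
    res = diagnostic_accuracy([True, False, True], [True, False, True])
    assert res.sensitivity == 100.0 and res.specificity == 100.0
    res = diagnostic_accuracy([False] * 20, [False] * 19 + [True])
    assert not res.sensitivity_defined
    assert res.specificity == pytest.approx(95.0)
    assert res.specificity_ci == (pytest.approx(75.13, abs=0.005), pytest.approx(99.87, abs=0.005))


@given(st.integers(0, 500))
def test_diagnostic_counts_conserved(seed):
    rng = np.random.default_rng(seed)
    truth = rng.random(20) < 0.5
    pred = rng.random(20) < 0.5
    res = diagnostic_accuracy(truth, pred)
    assert res.tp + res.fn == int(truth.sum())
    assert res.tn + res.fp == int((~truth).sum())


# ---------------------------------------------------------------------------
# t test

def test_two_sample_t_identical_and_degenerate():
    res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.t == pytest.approx(0.0) and res.p_value == pytest.approx(1.0)
    res = two_sample_t([0.0, 0.0, 0.0, 0.0], [1.0, 1.0, 1.0, 1.0])
    assert res.degenerate and np.isinf(res.t)


def test_two_sample_t_from_summary_statistics():
    """Published FP summary (3.57 +/- 4.68 vs 11.43 +/- 7.12, n=30 each):
    pooled |t| about 5.05, p far below .001."""
    res = two_sample_t_from_stats(3.57, 4.68, 30, 11.43, 7.12, 30)
    assert abs(res.t) == pytest.approx(5.05, abs=0.02)
    assert res.p_value < 0.001
    assert res.df == 58
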