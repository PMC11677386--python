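"""Agreement-statistic checks: closed-form and hand-computed values,
brute-force and library cross-checks, Monte-Carlo calibration, and the
structural invariants of each statistic."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score

from musclecompare import agreement as ag
from musclecompare.errors import DomainError


# ---------------------------------------------------------------------------
# Pearson

def test_pearson_values():
    x = np.arange(10.0)
    assert ag.pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
    assert ag.pearson_r(x, -x) == pytest.approx(-1.0)
    assert ag.pearson_r([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)


def test_pearson_constant_errors():
    with pytest.raises(DomainError):
        ag.pearson_r([1, 1, 1], [1, 2, 3])


# ---------------------------------------------------------------------------
# Lin's CCC

def test_ccc_identity():
    x = np.arange(20.0)
    res = ag.lin_ccc(x, x)
    assert res.rho_c == pytest.approx(1.0)
    assert res.category == "near perfect"


def test_ccc_constant_shift_closed_form():
    # for y = x + c: rho_c = 2 s² / (2 s² + c²); here s² = 2/3, c = 1 → 4/7
    res = ag.lin_ccc([1, 2, 3], [2, 3, 4])
    assert res.rho_c == pytest.approx(4 / 7)
    assert res.category == "poor"


def test_ccc_bivariate_normal_analytic():
    """Analytic CCC for a bivariate normal: 2ρσ²/(2σ² + Δμ²)."""
    rng = np.random.default_rng(123)
    n = 100_000
    rho = 0.9
    cov = [[1.0, rho], [rho, 1.0]]
    xy = rng.multivariate_normal([0.0, 0.5], cov, size=n)
    res = ag.lin_ccc(xy[:, 0], xy[:, 1])
    expected = 2 * rho / (1 + 1 + 0.25)
    assert res.rho_c == pytest.approx(expected, abs=0.01)
    assert res.ci_low < res.rho_c < res.ci_high


def test_ccc_ci_coverage_sanity():
    rng = np.random.default_rng(5)
    xy = rng.multivariate_normal([0, 0.3], [[1, 0.8], [0.8, 1]], size=200)
    res = ag.lin_ccc(xy[:, 0], xy[:, 1])
    assert res.ci_low < res.rho_c < res.ci_high
    assert -1 <= res.ci_low and res.ci_high <= 1


_grid_float = st.floats(-100, 100).map(lambda v: round(v, 3))


@given(st.lists(st.tuples(_grid_float, _grid_float), min_size=3, max_size=40))
def test_ccc_bounded_by_pearson(pairs):
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return
    rho_c = ag.lin_ccc(x, y).rho_c
    r = ag.pearson_r(x, y)
    assert abs(rho_c) <= abs(r) + 1e-9


def test_ccc_equals_pearson_when_moments_match():
    # equal means and variances → CCC = r exactly
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([2.0, 1.0, 4.0, 3.0])  # same mean and variance as x
    assert ag.lin_ccc(x, y).rho_c == pytest.approx(ag.pearson_r(x, y))


def test_ccc_category_bands():
    assert ag.ccc_category(0.995) == "near perfect"
    assert ag.ccc_category(0.97) == "substantial"
    assert ag.ccc_category(0.92) == "moderate"
    assert ag.ccc_category(0.80) == "poor"


# ---------------------------------------------------------------------------
# Cohen's kappa

def test_kappa_perfect():
    a = [0, 1] * 20
    res = ag.cohen_kappa(a, a)
    assert res.kappa == pytest.approx(1.0)


def test_kappa_hand_value():
    # 2x2 table [[40, 10], [10, 40]] → p_o = 0.8, p_e = 0.5, kappa = 0.6
    a = [0] * 50 + [1] * 50
    b = [0] * 40 + [1] * 10 + [0] * 10 + [1] * 40
    res = ag.cohen_kappa(a, b)
    assert res.kappa == pytest.approx(0.6)
    assert res.p_observed == pytest.approx(0.8)
    assert res.p_expected == pytest.approx(0.5)
    assert res.p_value < 1e-6


def test_kappa_null_simulation():
    rng = np.random.default_rng(42)
    a = rng.integers(0, 2, 10_000)
    b = rng.integers(0, 2, 10_000)
    assert abs(ag.cohen_kappa(a, b).kappa) < 0.03


def _kappa_oracle(n00, n01, n10, n11):
    """Exact kappa by direct definition in rational arithmetic."""
    n = n00 + n01 + n10 + n11
    po = Fraction(n00 + n11, n)
    pe = (Fraction(n00 + n01, n) * Fraction(n00 + n10, n)
          + Fraction(n10 + n11, n) * Fraction(n01 + n11, n))
    return float((po - pe) / (1 - pe))


def test_kappa_brute_force_all_small_tables():
    """Matches exhaustive direct computation over all 2×2 tables with cell
    counts ≤ 6 (skipping tables where kappa is undefined)."""
    for n00 in range(7):
        for n01 in range(7):
            for n10 in range(7):
                for n11 in range(7):
                    n = n00 + n01 + n10 + n11
                    if n == 0:
                        continue
                    a = [0] * (n00 + n01) + [1] * (n10 + n11)
                    b = [0] * n00 + [1] * n01 + [0] * n10 + [1] * n11
                    if (n01 + n10 == 0 and (n00 == 0 or n11 == 0)):
                        with pytest.raises(DomainError):
                            ag.cohen_kappa(a, b)
                        continue
                    expected = _kappa_oracle(n00, n01, n10, n11)
                    assert ag.cohen_kappa(a, b).kappa == pytest.approx(expected)


def test_kappa_matches_sklearn_multiclass():
    rng = np.random.default_rng(7)
    a = rng.integers(0, 4, 500)
    b = np.where(rng.random(500) < 0.6, a, rng.integers(0, 4, 500))
    assert ag.cohen_kappa(a, b).kappa == pytest.approx(
        cohen_kappa_score(a, b), abs=1e-12
    )


# ---------------------------------------------------------------------------
# Bland–Altman

def test_bland_altman_constant_offset():
    ref = np.linspace(10, 30, 25)
    idx = ref - 2.5  # index underestimates by 2.5
    res = ag.bland_altman(ref, idx)
    assert res.bias == pytest.approx(2.5)
    assert res.sd_diff == pytest.approx(0.0)
    assert res.loa_low == pytest.approx(2.5)
    assert res.loa_high == pytest.approx(2.5)
    assert res.n_outside == 0
    assert res.slope == 0.0


def test_bland_altman_bias_is_mean_difference(study_frame):
    """bias = mean(reference) − mean(index) exactly — the identity that lets
    printed group means validate printed biases."""
    ref = study_frame["l3_sma"].to_numpy()
    idx = study_frame["hgs"].to_numpy()
    res = ag.bland_altman(ref, idx)
    assert res.bias == pytest.approx(ref.mean() - idx.mean(), rel=1e-12)


def test_bland_altman_printed_loa_identity():
    """bias 1.5 and SD 3.6 give LoA (−5.6, 8.6) at one decimal — the pattern
    used for whole-cohort reporting."""
    rng = np.random.default_rng(0)
    d = rng.normal(0, 1, 2000)
    d = (d - d.mean()) / d.std(ddof=1)  # exact mean 0, sd 1
    d = 1.5 + 3.6 * d
    ref = rng.uniform(15, 35, 2000)
    res = ag.bland_altman(ref + d, ref)
    assert res.bias == pytest.approx(1.5, abs=1e-9)
    assert round(res.loa_low, 1) == -5.6
    assert round(res.loa_high, 1) == 8.6


def test_bland_altman_monte_carlo_recovery():
    rng = np.random.default_rng(8)
    n = 10_000
    ref = rng.uniform(20, 60, n)
    idx = ref - rng.normal(2.0, 1.0, n)
    res = ag.bland_altman(ref, idx)
    se = 1.0 / np.sqrt(n)
    assert abs(res.bias - 2.0) < 3 * se
    assert res.pct_outside == pytest.approx(5.0, abs=1.0)


def test_bland_altman_loa_coverage():
    rng = np.random.default_rng(9)
    n = 100_000
    ref = rng.normal(50, 5, n)
    idx = ref + rng.normal(0, 2, n)
    res = ag.bland_altman(ref, idx)
    assert res.pct_outside == pytest.approx(5.0, abs=1.0)


def test_bland_altman_short_input():
    with pytest.raises(DomainError):
        ag.bland_altman([1, 2], [1, 2])


# ---------------------------------------------------------------------------
# Normality gate and location tests

def test_normality_gate():
    rng = np.random.default_rng(10)
    assert ag.normality_gate(rng.normal(size=200)) is True
    assert ag.normality_gate(rng.exponential(size=500)) is False
    with pytest.raises(DomainError):
        ag.normality_gate(np.ones(50))


def test_compare_location_identical_paired():
    x = np.arange(10.0)
    res = ag.compare_location(x, x, paired=True)
    assert res.test == "wilcoxon signed-rank"
    assert res.p_value == 1.0


def test_compare_location_selects_t_for_normal_groups():
    rng = np.random.default_rng(1)
    x = rng.normal(0, 1, 200)
    y = rng.normal(1, 1, 200)
    res = ag.compare_location(x, y, paired=False)
    assert res.test == "t-test"
    assert res.p_value < 1e-3


def test_compare_location_selects_rank_for_heavy_tails():
    rng = np.random.default_rng(12)
    x = rng.standard_cauchy(300)
    y = rng.standard_cauchy(300) + 2
    res = ag.compare_location(x, y, paired=False)
    assert res.test == "mann-whitney"


def test_compare_location_paired_gate():
    rng = np.random.default_rng(13)
    x = rng.normal(0, 1, 100)
    res = ag.compare_location(x + rng.normal(0.5, 0.2, 100), x, paired=True)
    assert res.test == "paired t-test"
    assert res.p_value < 1e-6


def test_compare_location_type_i_error():
    """Null rejection rate ≈ alpha for samples from the same normal."""
    rng = np.random.default_rng(14)
    reps, n, alpha = 2000, 30, 0.05
    rejections = 0
    for _ in range(reps):
        x = rng.normal(0, 1, n)
        y = rng.normal(0, 1, n)
        if ag.compare_location(x, y, paired=False, alpha=alpha).p_value < alpha:
            rejections += 1
    rate = rejections / reps
    # binomial SE at p=0.05, n=2000 is ~0.005; allow 4 SE
    assert rate == pytest.approx(alpha, abs=0.02)


def test_compare_location_empty_group():
    with pytest.raises(DomainError):
        ag.compare_location([], [1.0, 2.0], paired=False)
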