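"""Method-comparison statistics.

The verifiable core of the package: Lin's concordance correlation coefficient
(CCC), Cohen's kappa and the Bland–Altman analysis are implemented here from
their definitions rather than delegated to a statistics library.  Classic
test internals (Shapiro–Wilk, Wilcoxon/Mann–Whitney null distributions,
Levene, t-tests) are delegated to :mod:`scipy.stats`.

Conventions
-----------
* Bland–Altman differences are ``reference - index``; a positive bias means
  the index method *underestimates* the reference.
* Limits of agreement are ``bias ± 1.96 · SD(differences)`` with the sample
  (n−1) standard deviation.
* CCC uses population (1/n) moments per the original concordance definition;
  its 95% CI comes from the Fisher z-transform with the standard asymptotic
  variance.
* CCC agreement bands: > 0.99 "near perfect", 0.95–0.99 "substantial",
  0.90–0.95 "moderate", < 0.90 "poor".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError

__all__ = [
    "BlandAltmanResult",
    "CCCResult",
    "KappaResult",
    "LocationTestResult",
    "pearson_r",
    "lin_ccc",
    "ccc_category",
    "cohen_kappa",
    "bland_altman",
    "normality_gate",
    "compare_location",
]


def _as_pair(x, y, min_n: int = 3):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("inputs must be equal-length 1-d vectors")
    if x.size < min_n:
        raise DomainError(f"need at least {min_n} paired observations")
    return x, y


def pearson_r(x, y) -> float:
    """Product-moment correlation; errors on constant input."""
    x, y = _as_pair(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DomainError("pearson_r is undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def ccc_category(rho_c: float) -> str:
    """Agreement band for a concordance coefficient."""
    if rho_c > 0.99:
        return "near perfect"
    if rho_c >= 0.95:
        return "substantial"
    if rho_c >= 0.90:
        return "moderate"
    return "poor"


@dataclass(frozen=True)
class CCCResult:
    rho_c: float
    ci_low: float
    ci_high: float
    category: str
    n: int


def lin_ccc(x, y, alpha: float = 0.05) -> CCCResult:
    """Lin's concordance correlation coefficient with a Fisher-z CI.

    rho_c = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²) with population (1/n) moments.
    The CI uses Lin's asymptotic variance of atanh(rho_c); for |rho_c| = 1
    (exact agreement up to sign) the interval degenerates to the point itself.
    """
    x, y = _as_pair(x, y)
    n = x.size
    mx, my = x.mean(), y.mean()
    sx2 = float(np.mean((x - mx) ** 2))
    sy2 = float(np.mean((y - my) ** 2))
    sxy = float(np.mean((x - mx) * (y - my)))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0:
        raise DomainError("lin_ccc is undefined when both vectors are constant and equal")
    rho_c = 2.0 * sxy / denom

    if sx2 == 0 or sy2 == 0 or abs(rho_c) >= 1.0 - 1e-15:
        return CCCResult(rho_c, rho_c, rho_c, ccc_category(rho_c), n)

    r = sxy / math.sqrt(sx2 * sy2)
    u = (mx - my) / (sx2 * sy2) ** 0.25  # location-shift relative to scale
    # Lin (1989) asymptotic variance of the z-transformed CCC.
    var_z = (
        (1 - r**2) * rho_c**2 / ((1 - rho_c**2) * r**2)
        + 2 * rho_c**3 * (1 - rho_c) * u**2 / (r * (1 - rho_c**2) ** 2)
        - rho_c**4 * u**4 / (2 * r**2 * (1 - rho_c**2) ** 2)
    ) / (n - 2)
    z = math.atanh(rho_c)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    half = zcrit * math.sqrt(max(var_z, 0.0))
    return CCCResult(
        rho_c=rho_c,
        ci_low=math.tanh(z - half),
        ci_high=math.tanh(z + half),
        category=ccc_category(rho_c),
        n=n,
    )


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    p_observed: float
    p_expected: float
    p_value: float
    n: int


def cohen_kappa(a, b) -> KappaResult:
    """Unweighted Cohen's kappa from the k×k contingency table.

    The p-value tests kappa = 0 with the large-sample normal approximation
    (null standard error from the marginal proportions).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise DomainError("inputs must be equal-length non-empty 1-d vectors")
    labels = np.unique(np.concatenate([a, b]))
    k = labels.size
    idx = {lab: i for i, lab in enumerate(labels)}
    table = np.zeros((k, k))
    for ai, bi in zip(a, b):
        table[idx[ai], idx[bi]] += 1
    n = table.sum()
    p = table / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    p_o = float(np.trace(p))
    p_e = float(row @ col)
    if p_e >= 1.0 - 1e-12:
        raise DomainError("kappa is undefined when both raters are constant and equal")
    kappa = (p_o - p_e) / (1.0 - p_e)
    # Fleiss-style null SE for the significance test.
    se0_num = p_e + p_e**2 - float(np.sum(row * col * (row + col)))
    se0 = math.sqrt(max(se0_num, 0.0)) / ((1.0 - p_e) * math.sqrt(n))
    if se0 == 0:
        p_value = float("nan")
    else:
        z = kappa / se0
        p_value = float(2 * stats.norm.sf(abs(z)))
    return KappaResult(kappa, p_o, p_e, p_value, int(n))


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    slope: float
    slope_p: float
    n: int
    n_outside: int
    pct_outside: float


def bland_altman(reference, index) -> BlandAltmanResult:
    """Bland–Altman agreement between a reference and an index method.

    Differences are reference − index, so a positive bias means the index
    method underestimates.  The dose-dependent-bias regression fits the
    differences on the pairwise means by least squares; with zero-variance
    means (or zero-variance differences) the slope is 0 with p = 1.
    """
    ref, idx = _as_pair(reference, index)
    d = ref - idx
    means = (ref + idx) / 2.0
    n = d.size
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_low, loa_high = bias - 1.96 * sd, bias + 1.96 * sd
    if np.ptp(means) == 0 or np.ptp(d) == 0:
        slope, slope_p = 0.0, 1.0
    else:
        fit = stats.linregress(means, d)
        slope, slope_p = float(fit.slope), float(fit.pvalue)
    outside = int(np.sum((d < loa_low) | (d > loa_high)))
    return BlandAltmanResult(
        bias=bias, sd_diff=sd, loa_low=loa_low, loa_high=loa_high,
        slope=slope, slope_p=slope_p, n=n,
        n_outside=outside, pct_outside=100.0 * outside / n,
    )


def normality_gate(x, alpha: float = 0.05) -> bool:
    """Shapiro–Wilk gate: True iff the sample is compatible with normality."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise DomainError("normality_gate needs n >= 3")
    if np.ptp(x) == 0:
        raise DomainError("normality_gate is undefined for a constant sample")
    return bool(stats.shapiro(x).pvalue > alpha)


@dataclass(frozen=True)
class LocationTestResult:
    test: str
    statistic: float
    p_value: float


def _gate_or_false(x, alpha: float) -> bool:
    try:
        return normality_gate(x, alpha)
    except DomainError:
        return False


def compare_location(x, y, paired: bool, alpha: float = 0.05) -> LocationTestResult:
    """Normality-gated comparison of central tendency.

    Paired: paired t-test if the differences pass the Shapiro–Wilk gate, else
    the Wilcoxon signed-rank test (zero differences dropped; if every
    difference is zero the samples agree and p = 1).  Unpaired: two-sample
    t-test if both groups pass the gate and Levene's test finds homoscedastic
    variances, else the Mann–Whitney rank-sum test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DomainError("compare_location requires non-empty groups")
    if paired:
        if x.size != y.size:
            raise DomainError("paired comparison requires equal lengths")
        d = x - y
        if _gate_or_false(d, alpha):
            res = stats.ttest_rel(x, y)
            return LocationTestResult("paired t-test", float(res.statistic), float(res.pvalue))
        nz = d[d != 0]
        if nz.size == 0:
            return LocationTestResult("wilcoxon signed-rank", 0.0, 1.0)
        res = stats.wilcoxon(nz, zero_method="wilcox")
        return LocationTestResult("wilcoxon signed-rank", float(res.statistic), float(res.pvalue))
    normal = _gate_or_false(x, alpha) and _gate_or_false(y, alpha)
    if normal:
        homoscedastic = stats.levene(x, y).pvalue > alpha
        if homoscedastic:
            res = stats.ttest_ind(x, y)
            return LocationTestResult("t-test", float(res.statistic), float(res.pvalue))
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return LocationTestResult("mann-whitney", float(res.statistic), float(res.pvalue))
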