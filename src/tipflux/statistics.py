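"""Statistical layer: OLS with influence diagnostics, group tests, z-control.

Linear associations are summarized by Pearson/Spearman correlations and an
OLS fit with intercept; per-point influence is measured by Cook's distance
(threshold 4/N) and robustness by leave-one-out refits.  Two-group
comparisons follow a fixed decision tree: Shapiro-Wilk normality per group,
then Bartlett's variance test choosing Student's vs Welch's t test, falling
back to a one-sided Mann-Whitney U test when normality fails.  The lag-0
cross-correlation of standardized series (equal to Pearson r) rules out
fluorescence fluctuations caused by axial (z) drift of the signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import signal, stats


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    cooks_distances: np.ndarray
    influential: np.ndarray  # indices with Cook's distance > 4/N
    loo: list  # per left-out index: {"excluded", "pearson_r", "pearson_p", "slope"}


@dataclass
class GroupComparison:
    test_name: str  # "Student t" | "Welch t" | "Mann-Whitney U"
    p_value: float
    stars: str
    decision_path: dict = field(default_factory=dict)


def correlate_and_fit(x, y) -> RegressionResult:
    """OLS of y on x with correlation, Cook's-distance and leave-one-out diagnostics."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    cooks = res.get_influence().cooks_distance[0]
    influential = np.flatnonzero(cooks > 4.0 / n)
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    loo = []
    for i in range(n):
        keep = np.arange(n) != i
        xi, yi = x[keep], y[keep]
        pri = stats.pearsonr(xi, yi)
        fit_i = sm.OLS(yi, sm.add_constant(xi)).fit()
        loo.append(
            {
                "excluded": i,
                "pearson_r": float(pri.statistic),
                "pearson_p": float(pri.pvalue),
                "slope": float(fit_i.params[1]),
            }
        )
    return RegressionResult(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r2=float(res.rsquared),
        pearson_r=float(pr.statistic),
        pearson_p=float(pr.pvalue),
        spearman_rho=float(sr.statistic),
        spearman_p=float(sr.pvalue),
        cooks_distances=cooks,
        influential=influential,
        loo=loo,
    )


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(a, b, alpha: float = 0.05) -> GroupComparison:
    """Two-group test chosen by the Shapiro-Wilk / Bartlett decision tree.

    Both groups normal at level ``alpha``: Bartlett's test chooses Student's
    (equal variances) or Welch's t test.  Otherwise a one-sided Mann-Whitney U
    test in the direction of the observed mean difference.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if min(a.size, b.size) < 3:
        raise ValueError("each group needs at least 3 observations for Shapiro-Wilk")
    sw_a = stats.shapiro(a)
    sw_b = stats.shapiro(b)
    path = {"shapiro_a_p": float(sw_a.pvalue), "shapiro_b_p": float(sw_b.pvalue)}
    if sw_a.pvalue > alpha and sw_b.pvalue > alpha:
        bart = stats.bartlett(a, b)
        path["bartlett_p"] = float(bart.pvalue)
        equal_var = bart.pvalue > alpha
        t = stats.ttest_ind(a, b, equal_var=equal_var)
        name = "Student t" if equal_var else "Welch t"
        p = float(t.pvalue)
    else:
        alternative = "greater" if a.mean() > b.mean() else "less"
        path["mannwhitney_alternative"] = alternative
        mw = stats.mannwhitneyu(a, b, alternative=alternative)
        name = "Mann-Whitney U"
        p = float(mw.pvalue)
    return GroupComparison(name, p, significance_stars(p), path)


def cross_correlation_lag0(a, b) -> float:
    """Lag-0 coefficient of the normalized full cross-correlation.

    Both series are mean-centered and divided by their (population) standard
    deviation; the full cross-correlation is normalized by the point count,
    making the lag-0 value identical to Pearson's r.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size != b.size or a.size < 3:
        raise ValueError("series must have equal length >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance input")
    za = (a - a.mean()) / a.std()
    zb = (b - b.mean()) / b.std()
    cc = np.correlate(za, zb, mode="full") / a.size
    lags = signal.correlation_lags(a.size, b.size, mode="full")
    return float(cc[lags == 0][0])
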