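"""Statistical layer: pooled t-test, one-way ANOVA with Tukey HSD,
two-sample t-test power / sample size, and cross-replicate series
averaging via modified Akima interpolation.

Conventions
-----------
The two-sample t-test is the pooled-variance (Student) form with
``df = n_a + n_b - 2``; this is the form that reproduces the printed
significance levels of the rate-constant comparisons.  Tukey HSD p-values
come from the studentized range distribution; for two groups they reduce
exactly to the pooled t-test p-value.  Sample sizes are the smallest
integer ``n`` per group whose exact noncentral-t power reaches the
requested level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import interpolate, stats


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    mean_diff: float
    degenerate: bool = False


@dataclass
class AnovaTukeyResult:
    F: float
    df_between: int
    df_within: int
    p_anova: float
    #: list of (group_i, group_j, mean_diff, p_adj)
    pairwise: list = field(default_factory=list)


@dataclass
class PowerResult:
    n_per_group: int
    achieved_power: float


@dataclass
class AveragedSeries:
    grid_time_min: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_series: int


def ttest_pooled(a, b) -> TTestResult:
    """Two-sided, two-sample unpaired Student t-test with pooled variance.

    Parameters
    ----------
    a, b : array-like
        Samples, each with at least two finite values.

    Returns
    -------
    TTestResult
        ``t`` is signed as mean(a) - mean(b); ``p`` is two-sided from the
        t distribution with ``n_a + n_b - 2`` degrees of freedom.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples must be finite")
    na, nb = a.size, b.size
    df = na + nb - 2
    mean_diff = a.mean() - b.mean()
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    if sp2 == 0.0:
        # Degenerate: no within-sample spread at all.
        if mean_diff == 0.0:
            return TTestResult(t=0.0, df=df, p=1.0, mean_diff=0.0)
        return TTestResult(
            t=np.inf if mean_diff > 0 else -np.inf,
            df=df, p=0.0, mean_diff=mean_diff, degenerate=True,
        )
    t = mean_diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=df, p=float(p), mean_diff=float(mean_diff))


def anova_tukey(groups) -> AnovaTukeyResult:
    """One-way ANOVA followed by Tukey's HSD pairwise comparisons.

    Parameters
    ----------
    groups : sequence of array-like
        ``k >= 2`` groups, each with at least two values.

    Returns
    -------
    AnovaTukeyResult
        Omnibus F and p, plus ``k(k-1)/2`` pairwise entries
        ``(i, j, mean_i - mean_j, p_adj)`` with p adjusted via the
        studentized range distribution.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if g.size < 2:
            raise ValueError("every group needs at least 2 values")
    ns = np.array([g.size for g in groups])
    n_total = int(ns.sum())
    grand = np.concatenate(groups).mean()
    means = np.array([g.mean() for g in groups])
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    df_between = k - 1
    df_within = n_total - k
    ms_within = ss_within / df_within
    if ms_within == 0.0:
        F = 0.0 if ss_between == 0.0 else np.inf
        p_anova = 1.0 if ss_between == 0.0 else 0.0
    else:
        F = (ss_between / df_between) / ms_within
        p_anova = float(stats.f.sf(F, df_between, df_within))

    pairwise = []
    for i, j in combinations(range(k), 2):
        diff = means[i] - means[j]
        if ms_within == 0.0:
            p_adj = 1.0 if diff == 0.0 else 0.0
        else:
            se = np.sqrt(ms_within / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(diff) / se
            p_adj = float(np.clip(stats.studentized_range.sf(q, k, df_within), 0, 1))
        pairwise.append((i, j, float(diff), p_adj))
    return AnovaTukeyResult(
        F=float(F), df_between=df_between, df_within=df_within,
        p_anova=float(p_anova), pairwise=pairwise,
    )


def power_two_t(n: int, effect_size: float, alpha: float = 0.05) -> float:
    """Exact power of the two-sided two-sample pooled t-test.

    ``effect_size`` is |mu0 - mu1| / sd; ``n`` is the per-group size.
    Power is computed from the noncentral t distribution with
    ``df = 2n - 2`` and noncentrality ``effect_size * sqrt(n / 2)``.
    """
    if n < 2:
        return 0.0
    df = 2 * n - 2
    nc = effect_size * np.sqrt(n / 2.0)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


def sample_size_two_t(mu0: float, mu1: float, sd: float,
                      power: float = 0.80, alpha: float = 0.05,
                      n_max: int = 1_000_000) -> PowerResult:
    """Minimal per-group n for a two-sided two-sample unpaired t-test.

    Searches for the smallest integer ``n`` such that the exact
    noncentral-t power at significance ``alpha`` reaches ``power``.

    Raises
    ------
    ValueError
        If the effect size is zero or parameters are out of range.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    if mu0 == mu1:
        raise ValueError("effect size is zero; sample size undefined")
    if not (0 < alpha < power < 1):
        raise ValueError("require 0 < alpha < power < 1")
    d = abs(mu0 - mu1) / sd
    # Bracket with the normal approximation, then walk to the exact minimum.
    za = stats.norm.ppf(1 - alpha / 2.0)
    zb = stats.norm.ppf(power)
    n = max(2, int(np.floor(2.0 * ((za + zb) / d) ** 2)) - 2)
    while n <= n_max and power_two_t(n, d, alpha) < power:
        n += 1
    if n > n_max:
        raise ValueError("required sample size exceeds n_max")
    while n > 2 and power_two_t(n - 1, d, alpha) >= power:
        n -= 1
    return PowerResult(n_per_group=n, achieved_power=power_two_t(n, d, alpha))


def akima_average(series, grid_step_min: float | None = None) -> AveragedSeries:
    """Average replicate time series on a common grid.

    Each series is resampled by modified Akima ("makima") cubic Hermite
    interpolation onto a shared time grid restricted to the interval
    covered by every series, then averaged pointwise with the standard
    error of the mean.

    Parameters
    ----------
    series : sequence of (t, y)
        At least two series, each with at least four samples; ``t`` in
        minutes, strictly increasing.
    grid_step_min : float, optional
        Grid spacing; defaults to the median sampling interval across
        all series.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 series")
    cleaned = []
    for t, y in series:
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        if t.size < 4:
            raise ValueError("each series needs at least 4 points")
        order = np.argsort(t)
        cleaned.append((t[order], y[order]))
    t_lo = max(t[0] for t, _ in cleaned)
    t_hi = min(t[-1] for t, _ in cleaned)
    if t_hi <= t_lo:
        raise ValueError("series share no common time interval")
    if grid_step_min is None:
        grid_step_min = float(np.median(np.concatenate(
            [np.diff(t) for t, _ in cleaned])))
    grid = np.arange(t_lo, t_hi + grid_step_min * 1e-9, grid_step_min)
    resampled = np.empty((len(cleaned), grid.size))
    for i, (t, y) in enumerate(cleaned):
        interp = interpolate.Akima1DInterpolator(t, y, method="makima")
        resampled[i] = interp(grid)
    mean = resampled.mean(axis=0)
    sem = resampled.std(axis=0, ddof=1) / np.sqrt(len(cleaned))
    return AveragedSeries(grid_time_min=grid, mean=mean, sem=sem,
                          n_series=len(cleaned))
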