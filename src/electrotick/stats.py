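"""Statistical procedures used in the tick-attraction analyses.

Covers the complete toolkit of the study's quantification: Pearson's
chi-square test of independence with Bonferroni-corrected adjusted
standardized residuals for the lift-outcome table, Wald binomial confidence
intervals for outcome proportions, percentile-bootstrap confidence intervals
of the median (for the non-normal humidity and threshold-voltage data),
Mann-Whitney U with permutation p-values (the data contain ties, so the
asymptotic null is replaced by label permutation, exhaustive when feasible),
the classical (mean-centred) Levene test for equality of variances, and
regression through the origin with the free-intercept comparison used for
the distance-voltage threshold law.

All randomized procedures take an explicit seed and are bit-reproducible.
Two-tailed permutation p-values count permutations whose statistic deviates
from the null mean by at least the observed deviation, observed arrangement
included, so p is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

#: two-sided 95% normal quantile used for Wald intervals
Z_95 = 1.959964


@dataclass
class ContingencyTable:
    """Outcome counts (rows = groups, columns = outcomes)."""

    counts: np.ndarray
    row_labels: Tuple[str, ...]
    col_labels: Tuple[str, ...]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or min(self.counts.shape) < 2:
            raise ValueError("contingency table must be at least 2x2")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.sum() == 0:
            raise ValueError("grand total must be positive")
        if len(self.row_labels) != self.counts.shape[0] or len(
            self.col_labels
        ) != self.counts.shape[1]:
            raise ValueError("label lengths must match the table shape")

    @classmethod
    def from_string(cls, text: str, row_labels=None, col_labels=None):
        """Parse e.g. ``"15,3,2;0,1,19"`` (rows separated by ';')."""
        counts = np.array(
            [[int(v) for v in row.split(",")] for row in text.split(";")]
        )
        r, c = counts.shape
        return cls(
            counts,
            tuple(row_labels or (f"row{i}" for i in range(r))),
            tuple(col_labels or (f"col{j}" for j in range(c))),
        )

    def proportions(self, axis: int = 1) -> np.ndarray:
        return self.counts / self.counts.sum(axis=axis, keepdims=True)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.row_labels), columns=list(self.col_labels)
        )


@dataclass
class TestResult:
    """Statistic, degrees of freedom (or permutation count) and p-value.

    ``residuals``/``residual_p`` are per-cell adjusted standardized residuals
    and their Bonferroni-corrected p-values (chi-square test only); ``ci``
    carries interval bounds where the procedure produces one.
    """

    statistic: float
    p_value: float
    df: Optional[Tuple[int, ...]] = None
    n_permutations: Optional[int] = None
    exhaustive: bool = False
    residuals: Optional[np.ndarray] = None
    residual_p: Optional[np.ndarray] = None
    ci: Optional[Tuple[float, float]] = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {"statistic": float(self.statistic), "p_value": float(self.p_value)}
        if self.df is not None:
            d["df"] = list(self.df)
        if self.n_permutations is not None:
            d["n_permutations"] = int(self.n_permutations)
            d["exhaustive"] = self.exhaustive
        if self.residuals is not None:
            d["adjusted_residuals"] = np.asarray(self.residuals).tolist()
            d["residual_p_bonferroni"] = np.asarray(self.residual_p).tolist()
        if self.ci is not None:
            d["ci"] = [float(self.ci[0]), float(self.ci[1])]
        for k, v in self.extra.items():
            d[k] = np.asarray(v).tolist() if isinstance(v, np.ndarray) else v
        return d


# ---------------------------------------------------------------------------
# chi-square with post-hoc residuals
# ---------------------------------------------------------------------------

def chi_square_independence(table: ContingencyTable) -> TestResult:
    """Pearson chi-square test of independence with post-hoc residuals.

    The per-cell adjusted standardized residual is
    (O - E) / sqrt(E (1 - row_total/N) (1 - col_total/N)); its two-sided
    normal p-value is Bonferroni-corrected by the number of cells.
    """
    obs = table.counts
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("degenerate table: a zero marginal leaves E undefined")
    chi2, p, dof, expected = sps.chi2_contingency(obs, correction=False)
    n = obs.sum()
    row_p = obs.sum(axis=1, keepdims=True) / n
    col_p = obs.sum(axis=0, keepdims=True) / n
    adj = (obs - expected) / np.sqrt(expected * (1 - row_p) * (1 - col_p))
    cell_p = 2 * sps.norm.sf(np.abs(adj))
    bonf = np.minimum(cell_p * obs.size, 1.0)
    r, c = obs.shape
    return TestResult(
        statistic=float(chi2),
        p_value=float(p),
        df=((r - 1) * (c - 1),),
        residuals=adj,
        residual_p=bonf,
        extra={"expected": expected, "n": int(n)},
    )


# ---------------------------------------------------------------------------
# confidence intervals
# ---------------------------------------------------------------------------

def wald_binomial_ci(successes: int, n: int, level: float = 0.95) -> TestResult:
    """Wald (normal-approximation) binomial confidence interval."""
    if not 0 <= successes <= n or n <= 0:
        raise ValueError("require 0 <= successes <= n, n > 0")
    p_hat = successes / n
    z = Z_95 if level == 0.95 else sps.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(p_hat * (1 - p_hat) / n)
    return TestResult(
        statistic=p_hat,
        p_value=np.nan,
        ci=(p_hat - half, p_hat + half),
        extra={"half_width": float(half), "level": level, "n": n},
    )


def bootstrap_median_ci(
    x: Sequence[float],
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
) -> TestResult:
    """Percentile bootstrap confidence interval of the median."""
    x = np.asarray(x, float)
    if x.size == 0:
        raise ValueError("x must be non-empty")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    medians = np.median(x[idx], axis=1)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(medians, [alpha, 1 - alpha])
    return TestResult(
        statistic=float(np.median(x)),
        p_value=np.nan,
        ci=(float(lo), float(hi)),
        extra={"n_boot": n_boot, "level": level},
    )


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

def _rank_sum_U(ranks_x_sum: float, n_x: int) -> float:
    return ranks_x_sum - n_x * (n_x + 1) / 2


def mann_whitney_permutation(
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = 10_000,
    seed: int = 0,
    exhaustive_limit: int = 20_000,
) -> TestResult:
    """Mann-Whitney U with a two-tailed permutation p-value.

    Ties get average (mid) ranks.  When the number of distinct group
    assignments C(n+m, n) is at most ``exhaustive_limit`` the permutation
    null is enumerated exactly; otherwise ``n_perm`` random permutations are
    drawn (the observed arrangement is counted, so p >= 1/(n_perm+1)).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    U_obs = _rank_sum_U(ranks[:n].sum(), n)
    mu = n * m / 2.0
    dev_obs = abs(U_obs - mu)
    total = comb(n + m, n)
    if total <= exhaustive_limit:
        idx = np.fromiter(
            (i for c in combinations(range(n + m), n) for i in c), dtype=np.intp
        ).reshape(total, n)
        U_all = _rank_sum_U(ranks[idx].sum(axis=1), n)
        count = int(np.sum(np.abs(U_all - mu) >= dev_obs - 1e-12))
        return TestResult(
            statistic=float(U_obs),
            p_value=count / total,
            n_permutations=total,
            exhaustive=True,
            extra={"U_mean": mu},
        )
    rng = np.random.default_rng(seed)
    # vectorised random assignments: first n positions of random orderings
    U_perm = np.empty(n_perm)
    chunk = max(1, int(2e6 // (n + m)))
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        order = np.argsort(rng.random((k, n + m)), axis=1)[:, :n]
        U_perm[done: done + k] = _rank_sum_U(ranks[order].sum(axis=1), n)
        done += k
    count = int(np.sum(np.abs(U_perm - mu) >= dev_obs - 1e-12))
    return TestResult(
        statistic=float(U_obs),
        p_value=(count + 1) / (n_perm + 1),
        n_permutations=n_perm,
        exhaustive=False,
        extra={"U_mean": mu},
    )


def levene_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Classical Levene test (deviations from the group means)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    dx = np.abs(x - x.mean())
    dy = np.abs(y - y.mean())
    if dx.max() == 0 and dy.max() == 0:
        raise ValueError("degenerate: no within-group deviation in any group")
    with np.errstate(divide="ignore", invalid="ignore"):
        stat, p = sps.levene(x, y, center="mean")
    if not np.isfinite(stat):  # zero within-group variance of |deviations|
        stat, p = np.inf, 0.0
    return TestResult(
        statistic=float(stat), p_value=float(p), df=(1, x.size + y.size - 2)
    )


# ---------------------------------------------------------------------------
# regression through the origin
# ---------------------------------------------------------------------------

@dataclass
class OriginFit:
    """Zero-intercept fit with the free-intercept comparison.

    ``r_squared`` is the uncentred R^2 (about zero), the standard convention
    for forced-origin regression; the F statistic uses df (1, n-1).  The
    free-intercept model's intercept confidence interval and the ANOVA
    comparison of the two models indicate whether a zero intercept is
    tenable.
    """

    slope: float
    r_squared: float
    f_stat: float
    df: Tuple[int, int]
    p_value: float
    n: int
    slope_stderr: float
    free_slope: float
    free_intercept: float
    free_intercept_ci: Tuple[float, float]
    free_r_squared: float
    anova_f: float
    anova_p: float

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "slope", "r_squared", "f_stat", "p_value", "n", "slope_stderr",
            "free_slope", "free_intercept", "free_r_squared", "anova_f",
            "anova_p",
        )}
        d["df"] = list(self.df)
        d["free_intercept_ci"] = list(self.free_intercept_ci)
        return d


def regression_through_origin(x: Sequence[float], y: Sequence[float]) -> OriginFit:
    """Least-squares line forced through the origin, y = G x.

    The closed-form slope is sum(xy)/sum(x^2).  Also fits the ordinary
    free-intercept model and reports its intercept confidence interval and
    the nested-model ANOVA comparison (does freeing the intercept reduce the
    residual sum of squares significantly?).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n < 2 or y.size != n:
        raise ValueError("need at least 2 paired points")
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("rank deficient: all x are zero")
    slope = float(np.sum(x * y)) / sxx
    fitted = slope * x
    rss = float(np.sum((y - fitted) ** 2))
    tss = float(np.sum(y * y))  # uncentred
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    df = (1, n - 1)
    mse = rss / df[1] if df[1] > 0 else np.nan
    f = (float(np.sum(fitted**2)) / 1.0) / mse if mse > 0 else np.inf
    p = float(sps.f.sf(f, *df)) if np.isfinite(f) else 0.0
    stderr = float(np.sqrt(mse / sxx)) if mse > 0 else 0.0

    if np.ptp(x) > 0 and n > 2:
        free = sm.OLS(y, sm.add_constant(x)).fit()
        rss_free = float(free.ssr)
        ci = free.conf_int(alpha=0.05)
        anova_f = (
            (rss - rss_free) / (rss_free / (n - 2)) if rss_free > 0 else np.inf
        )
        anova_p = float(sps.f.sf(anova_f, 1, n - 2))
        free_slope = float(free.params[1])
        free_intercept = float(free.params[0])
        free_ci = (float(ci[0][0]), float(ci[0][1]))
        free_r2 = float(free.rsquared)
    else:  # free-intercept model not identifiable
        free_slope = np.nan
        free_intercept = np.nan
        free_ci = (np.nan, np.nan)
        free_r2 = np.nan
        anova_f = np.nan
        anova_p = np.nan
    return OriginFit(
        slope=slope,
        r_squared=r2,
        f_stat=f,
        df=df,
        p_value=p,
        n=n,
        slope_stderr=stderr,
        free_slope=free_slope,
        free_intercept=free_intercept,
        free_intercept_ci=free_ci,
        free_r_squared=free_r2,
        anova_f=float(anova_f),
        anova_p=float(anova_p) if np.isfinite(anova_f) else np.nan,
    )
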