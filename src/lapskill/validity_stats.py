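"""Construct-validity statistics: group comparisons of MAPs and questionnaires.

The study design behind these routines is a two-group (expert vs novice)
comparison of a nine-component feature vector, followed by univariate
comparisons per component:

* an overall two-group MANOVA — for two groups every classical MANOVA
  statistic (Wilks, Pillai, Hotelling–Lawley, Roy) coincides with
  Hotelling's T², which is what :func:`hotelling_t2` computes, with the
  exact F transformation for the p-value;
* per-MAP one-way two-group ANOVA, which is identical to the pooled-variance
  t-test (F = t²); :func:`t_from_summary` computes it from printed group
  summaries (n, mean, SD) so published tables can be re-analysed without raw
  data.  A Welch variant is available but non-default;
* two-sided Mann–Whitney U for ordinal questionnaire items, with an exact
  enumeration null for small samples and a tie- and continuity-corrected
  normal approximation otherwise;
* Pearson χ² (no continuity correction) and Fisher's exact test for
  categorical tables, via scipy.

No multiple-testing correction is applied across the nine MAPs by default,
matching the analysis convention the reference tables were produced under;
an optional Holm adjustment is available in :func:`compare_all_maps`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .motion_metrics import MAP_NAMES, TrialMetrics

__all__ = [
    "GroupSummary",
    "TestResult",
    "t_from_summary",
    "hotelling_t2",
    "mann_whitney_u",
    "chi_square_test",
    "fisher_exact",
    "compare_all_maps",
    "holm_adjust",
    "summarize",
]

#: Largest smaller-sample size for which the Mann-Whitney null is enumerated.
MW_EXACT_MIN_N = 8
#: Enumeration budget: number of group labelings the exact path may visit.
MW_EXACT_MAX_COMBINATIONS = 500_000


@dataclass(frozen=True)
class GroupSummary:
    """Sample size, mean and SD of one group on one variable."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summary needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test (always two-sided)."""

    statistic: float
    statistic_name: str
    df: float | tuple
    p: float
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p-value out of range: {self.p!r}")


def summarize(x: Sequence[float]) -> GroupSummary:
    """Sample n, mean, SD (ddof=1) of a raw sample."""
    a = np.asarray(x, dtype=float)
    return GroupSummary(n=len(a), mean=float(a.mean()), sd=float(a.std(ddof=1)))


# ---------------------------------------------------------------------------
# univariate group comparison
# ---------------------------------------------------------------------------

def t_from_summary(a: GroupSummary, b: GroupSummary,
                   variant: str = "pooled") -> TestResult:
    """Two-sample t-test from group summaries.

    ``variant='pooled'`` (default) is the equal-variance test, identical to
    a two-group one-way ANOVA via F = t²; ``variant='welch'`` uses the
    Satterthwaite degrees of freedom.  If both SDs are zero the test is
    degenerate: equal means give t = 0, p = 1; unequal means give p = 0.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError(f"variant must be pooled|welch, got {variant!r}")
    if a.sd == 0.0 and b.sd == 0.0:
        if a.mean == b.mean:
            return TestResult(0.0, "t", float(a.n + b.n - 2), 1.0, "degenerate")
        return TestResult(math.inf, "t", float(a.n + b.n - 2), 0.0, "degenerate")
    t, p = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = float(a.n + b.n - 2)
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return TestResult(float(t), "t", df, float(p), variant)


# ---------------------------------------------------------------------------
# multivariate comparison
# ---------------------------------------------------------------------------

def hotelling_t2(X_a: np.ndarray, X_b: np.ndarray,
                 ridge: float = 0.0) -> TestResult:
    """Two-sample Hotelling T² with the exact F approximation.

    ``T² = (n_a n_b / n) d' S⁻¹ d`` with ``d`` the mean difference and ``S``
    the pooled covariance; ``F = (n − p − 1) / (p (n − 2)) · T²`` on
    ``(p, n − p − 1)`` degrees of freedom.  A singular pooled covariance is
    ridge-regularised (relative to the mean diagonal) and the result's
    ``method`` is flagged accordingly.
    """
    X_a = np.atleast_2d(np.asarray(X_a, dtype=float))
    X_b = np.atleast_2d(np.asarray(X_b, dtype=float))
    if X_a.shape[1] != X_b.shape[1]:
        raise ValueError("feature dimension mismatch")
    n_a, n_b, p = len(X_a), len(X_b), X_a.shape[1]
    n = n_a + n_b
    if n - 2 < p:
        raise ValueError(f"need n_a + n_b - 2 >= p, got n={n}, p={p}")
    d = X_a.mean(axis=0) - X_b.mean(axis=0)
    S = ((n_a - 1) * np.cov(X_a, rowvar=False) +
         (n_b - 1) * np.cov(X_b, rowvar=False)) / (n - 2)
    S = np.atleast_2d(S)
    method = "F-approx"
    lam = ridge
    if lam == 0.0 and (not np.isfinite(np.linalg.cond(S)) or np.linalg.cond(S) > 1e12):
        lam = 1e-8
    if lam > 0.0:
        S = S + lam * np.mean(np.diag(S)) * np.eye(p)
        method = "F-approx+ridge"
    t2 = float(n_a * n_b / n * d @ np.linalg.solve(S, d))
    df2 = n - p - 1
    f = t2 * df2 / (p * (n - 2))
    pval = float(stats.f.sf(f, p, df2))
    return TestResult(t2, "T2", (float(p), float(df2)), pval, method)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x: #(x > y) + ½·ties, via midranks."""
    nx, ny = len(x), len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    rx = ranks[:nx].sum()
    return float(rx - nx * (nx + 1) / 2)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann–Whitney U test.

    When the smaller sample has at most :data:`MW_EXACT_MIN_N` observations
    (and the enumeration budget allows), the null distribution of
    ``U_min = min(U_x, U_y)`` is built by enumerating every assignment of
    the pooled values to groups — which handles ties exactly — and the
    p-value is ``P(U_min ≤ observed)``.  Otherwise a normal approximation
    with midrank tie correction and a 0.5 continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    nx, ny = len(x), len(y)
    ux = _u_statistic(x, y)
    uy = nx * ny - ux
    u_obs = min(ux, uy)

    if min(nx, ny) <= MW_EXACT_MIN_N and comb(nx + ny, nx) <= MW_EXACT_MAX_COMBINATIONS:
        pooled = np.concatenate([x, y])
        idx_all = range(nx + ny)
        count = 0
        total = comb(nx + ny, nx)
        for ix in itertools.combinations(idx_all, nx):
            mask = np.zeros(nx + ny, dtype=bool)
            mask[list(ix)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            if min(u, nx * ny - u) <= u_obs + 1e-12:
                count += 1
        return TestResult(u_obs, "U", float(nx * ny), count / total, "exact")

    # normal approximation with tie + continuity correction
    pooled = np.concatenate([x, y])
    _, t_counts = np.unique(pooled, return_counts=True)
    n = nx + ny
    tie_term = ((t_counts**3 - t_counts).sum()) / (n * (n - 1))
    sigma2 = nx * ny / 12 * ((n + 1) - tie_term)
    mu = nx * ny / 2
    if sigma2 <= 0:  # all values tied
        return TestResult(u_obs, "U", float(nx * ny), 1.0, "normal-approx")
    z = (abs(ux - mu) - 0.5) / math.sqrt(sigma2)
    z = max(z, 0.0)
    p = min(1.0, 2 * stats.norm.sf(z))
    return TestResult(u_obs, "U", float(nx * ny), p, "normal-approx")


# ---------------------------------------------------------------------------
# categorical tables
# ---------------------------------------------------------------------------

def chi_square_test(table) -> TestResult:
    """Pearson χ² test of independence on an r×c count table, without
    continuity correction."""
    t = np.asarray(table, dtype=float)
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin")
    res = stats.chi2_contingency(t, correction=False)
    return TestResult(float(res.statistic), "chi2", float(res.dof),
                      float(res.pvalue), "chi2-pearson")


def fisher_exact(table) -> TestResult:
    """Fisher's exact test on a 2×2 table; the two-sided p-value sums the
    probabilities of all tables no more probable than the observed one."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("Fisher's exact test needs a 2x2 table")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    res = stats.fisher_exact(t, alternative="two-sided")
    return TestResult(float(res.statistic), "odds-ratio", 1.0,
                      float(res.pvalue), "exact")


# ---------------------------------------------------------------------------
# per-MAP comparison table
# ---------------------------------------------------------------------------

def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(running, 1.0)
    return adj


def compare_all_maps(novice: Sequence[TrialMetrics],
                     expert: Sequence[TrialMetrics],
                     variant: str = "pooled",
                     holm: bool = False) -> tuple[TestResult, pd.DataFrame]:
    """Full construct-validity comparison of two MAP cohorts.

    Returns the overall Hotelling T² result and a nine-row DataFrame (one
    per MAP, canonical order) with columns ``map, novice_n, novice_mean,
    novice_sd, expert_n, expert_mean, expert_sd, statistic, df, p`` and,
    when ``holm=True``, ``p_holm``.
    """
    if len(novice) < 2 or len(expert) < 2:
        raise ValueError("need at least 2 trials per group")
    X_n = np.array([t.maps.as_array() for t in novice])
    X_e = np.array([t.maps.as_array() for t in expert])
    overall = hotelling_t2(X_n, X_e)

    rows = []
    for j, name in enumerate(MAP_NAMES):
        sn = summarize(X_n[:, j])
        se = summarize(X_e[:, j])
        res = t_from_summary(sn, se, variant=variant)
        rows.append({
            "map": name,
            "novice_n": sn.n, "novice_mean": sn.mean, "novice_sd": sn.sd,
            "expert_n": se.n, "expert_mean": se.mean, "expert_sd": se.sd,
            "statistic": res.statistic, "df": res.df, "p": res.p,
        })
    table = pd.DataFrame(rows)
    if holm:
        table["p_holm"] = holm_adjust(table["p"].to_numpy())
    return overall, table
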