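"""Nonparametric statistical battery for session-level comparisons.

Two-sample tests (two-sided Wilcoxon signed-rank and Mann-Whitney U)
with exact small-sample enumeration, omnibus Friedman / Kruskal-Wallis
tests with tie correction, and the Steel-Dwass (all-pairs) and Steel
(many-to-one) rank-based post-hoc procedures.

Exact p values are computed by full enumeration — 2^n sign assignments
for the signed-rank test (n <= 15 after zero removal, ties mid-ranked),
all C(N, n_a) group assignments for Mann-Whitney (N <= 16), and all
products of within-block rank permutations for Friedman (k = 3,
n <= 8) — and fall back to tie-corrected normal / chi-square
approximations above those sizes.  The Steel-Dwass adjusted p refers
sqrt(2)·|z| of each pairwise rank-sum z to the studentized-range
distribution with k groups and infinite degrees of freedom; the Steel
adjusted p refers |z| to the maximum of k-1 equicorrelated (rho = 0.5)
standard normals, evaluated by seeded Monte-Carlo integration.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatResult",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "friedman",
    "kruskal_wallis",
    "steel_dwass",
    "steel",
    "studentized_range_sf_inf",
    "results_table",
]

EXACT_WILCOXON_MAX_N = 15
EXACT_MANNWHITNEY_MAX_N = 16


@dataclass
class StatResult:
    """Outcome of one test, including per-pair results for post-hocs."""

    test_name: str
    statistic: float
    p_value: float
    n: tuple
    method: str
    comparisons: list = field(default_factory=list)

    def __post_init__(self) -> None:
        assert 0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)


@dataclass
class PairResult:
    pair: tuple
    statistic: float
    p_value: float


def _clean(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in sample")
    return x


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def wilcoxon_signed_rank(x, y=None, zero_method: str = "wilcox") -> StatResult:
    """Two-sided Wilcoxon signed-rank test on paired data.

    ``x`` and ``y`` are paired vectors (or ``x`` the differences).  Zero
    differences are dropped (``zero_method="wilcox"``); ``"pratt"``
    ranks them with the rest before dropping.  The statistic W is the
    sum of ranks of positive differences; p is exact (full 2^n sign
    enumeration, mid-ranked ties) for n <= 15 and a tie-corrected normal
    approximation otherwise.
    """
    d = _clean(x) if y is None else _clean(x) - _clean(y)
    if zero_method not in ("wilcox", "pratt"):
        raise ValueError(f"unknown zero_method {zero_method!r}")
    nz = d != 0
    if not nz.any():
        warnings.warn("all paired differences are zero; p = 1")
        return StatResult("wilcoxon_signed_rank", 0.0, 1.0, (0,), "degenerate")
    if zero_method == "wilcox":
        d = d[nz]
        ranks = sps.rankdata(np.abs(d))
    else:  # pratt: rank zeros with the rest, then drop them
        ranks_all = sps.rankdata(np.abs(d))
        ranks = ranks_all[nz]
        d = d[nz]
    n = d.size
    if n < 3:
        raise ValueError(f"need >= 3 nonzero differences, got {n}")
    w = float(ranks[d > 0].sum())
    total = float(ranks.sum())
    mu = total / 2.0

    if n <= EXACT_WILCOXON_MAX_N:
        signs = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
        w_all = signs @ ranks
        p = float(np.mean(np.abs(w_all - mu) >= np.abs(w - mu) - 1e-12))
        return StatResult("wilcoxon_signed_rank", w, p, (n,), "exact")

    # normal approximation with tie correction on shared |d| ranks
    _, counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - float(((counts**3 - counts)).sum()) / 48.0
    z = (w - mu) / np.sqrt(var)
    p = min(1.0, 2.0 * float(sps.norm.sf(abs(z))))
    return StatResult("wilcoxon_signed_rank", w, p, (n,), "asymptotic")


# ---------------------------------------------------------------------------
# Mann-Whitney U


def _mw_u(a: np.ndarray, b: np.ndarray) -> float:
    """U statistic of group a (ties count 1/2)."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    ra = ranks[: a.size].sum()
    return float(ra - a.size * (a.size + 1) / 2.0)


def mann_whitney_u(a, b) -> StatResult:
    """Two-sided Mann-Whitney U test on two independent samples.

    Exact p by enumeration of all C(N, n_a) assignments of the pooled
    values for N <= 16 (valid with ties via mid-ranks); tie-corrected
    normal approximation for larger samples.  Two-sidedness uses the
    symmetry of U around n_a·n_b/2.
    """
    a, b = _clean(a), _clean(b)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    na, nb = a.size, b.size
    N = na + nb
    u = _mw_u(a, b)
    mu = na * nb / 2.0

    if N <= EXACT_MANNWHITNEY_MAX_N:
        pooled = np.concatenate([a, b])
        ranks = sps.rankdata(pooled)
        offset = na * (na + 1) / 2.0
        dev = abs(u - mu)
        hits = 0
        total = comb(N, na)
        for idx in itertools.combinations(range(N), na):
            ua = ranks[list(idx)].sum() - offset
            if abs(ua - mu) >= dev - 1e-12:
                hits += 1
        return StatResult("mann_whitney_u", u, hits / total, (na, nb), "exact")

    pooled = np.concatenate([a, b])
    _, counts = np.unique(pooled, return_counts=True)
    tie = float(((counts**3 - counts)).sum())
    var = na * nb / 12.0 * ((N + 1) - tie / (N * (N - 1)))
    z = (u - mu) / np.sqrt(var)
    p = min(1.0, 2.0 * float(sps.norm.sf(abs(z))))
    return StatResult("mann_whitney_u", u, p, (na, nb), "asymptotic")


# ---------------------------------------------------------------------------
# omnibus tests


def _friedman_stat(ranks: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square from within-block ranks (n × k)."""
    n, k = ranks.shape
    col_sums = ranks.sum(axis=0)
    s = float(((col_sums - n * (k + 1) / 2.0) ** 2).sum())
    tie = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        tie += float(((counts**3 - counts)).sum())
    denom = n * k * (k + 1) - tie / (k - 1)
    if denom <= 0:
        return 0.0
    return 12.0 * s / denom


def friedman(data, method: str = "auto") -> StatResult:
    """Friedman test on an ``n_blocks x k_treatments`` complete table.

    Tie-corrected chi-square approximation with k-1 degrees of freedom;
    an exact permutation reference (all k!^n products of within-block
    rank permutations) is available for k = 3 and n <= 8.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("friedman expects a 2-D blocks x treatments array")
    n, k = data.shape
    if k < 3:
        raise ValueError(f"need k >= 3 treatments, got {k}")
    bad = np.flatnonzero(~np.all(np.isfinite(data), axis=1))
    if bad.size:
        raise ValueError(f"incomplete block at row {bad[0]}")
    ranks = np.apply_along_axis(sps.rankdata, 1, data)
    stat = _friedman_stat(ranks)

    exact_ok = k == 3 and n <= 8
    if method == "exact" and not exact_ok:
        raise ValueError("exact Friedman supported for k = 3, n_blocks <= 8")
    if method == "exact":
        perms = list(itertools.permutations(range(k)))
        sums = np.zeros((1, k))
        for i in range(n):
            variants = np.stack([ranks[i, list(p)] for p in perms])  # (k!, k)
            sums = (sums[:, None, :] + variants[None, :, :]).reshape(-1, k)
        s_all = ((sums - n * (k + 1) / 2.0) ** 2).sum(axis=1)
        s_obs = float(((ranks.sum(axis=0) - n * (k + 1) / 2.0) ** 2).sum())
        p = float(np.mean(s_all >= s_obs - 1e-12))
        return StatResult("friedman", stat, p, (n, k), "exact")

    p = float(sps.chi2.sf(stat, k - 1)) if stat > 0 else 1.0
    return StatResult("friedman", stat, min(p, 1.0), (n, k), "asymptotic")


def kruskal_wallis(groups) -> StatResult:
    """Kruskal-Wallis H test (tie-corrected) on k >= 2 groups."""
    groups = [_clean(g) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    if np.ptp(np.concatenate(groups)) == 0:
        return StatResult("kruskal_wallis", 0.0, 1.0, tuple(g.size for g in groups), "degenerate")
    stat, p = sps.kruskal(*groups)
    return StatResult("kruskal_wallis", float(stat), float(p), tuple(g.size for g in groups), "asymptotic")


# ---------------------------------------------------------------------------
# studentized range (df = inf) and post-hoc procedures


def studentized_range_sf_inf(q: float, k: int, n_grid: int = 2001) -> float:
    """P(Q > q) for the range of k iid standard normals.

    Closed form as a 1-D integral, F(q) = k ∫ φ(z) [Φ(z) − Φ(z−q)]^{k−1} dz,
    evaluated by trapezoid on a fixed grid (absolute accuracy ~1e-9 —
    the infinite-df studentized-range tail used by the Steel-Dwass
    procedure).
    """
    if q <= 0:
        return 1.0
    z = np.linspace(-8.5, 8.5 + q, n_grid)
    integrand = k * sps.norm.pdf(z) * (sps.norm.cdf(z) - sps.norm.cdf(z - q)) ** (k - 1)
    cdf = float(np.trapezoid(integrand, z))
    return float(min(max(1.0 - cdf, 0.0), 1.0))


def studentized_range_crit_inf(alpha: float, k: int) -> float:
    """Critical value q with P(Q > q) = alpha (bisection on the sf)."""
    lo, hi = 1e-6, 20.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if studentized_range_sf_inf(mid, k) > alpha:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def pairwise_rank_z(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized two-sample rank-sum statistic with tie correction.

    z = (W - E[W]) / sd(W), W the rank sum of group ``a`` within the
    pooled pair.  This is the building block both Steel-type procedures
    standardize before referring to their family-wise null.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    N = na + nb
    ranks = sps.rankdata(np.concatenate([a, b]))
    w = float(ranks[:na].sum())
    e = na * (N + 1) / 2.0
    _, counts = np.unique(ranks, return_counts=True)
    tie = float(((counts**3 - counts)).sum())
    var = na * nb / 12.0 * ((N + 1) - tie / (N * (N - 1)))
    if var <= 0:
        return 0.0
    return (w - e) / np.sqrt(var)


def steel_dwass(groups, alpha: float = 0.05) -> StatResult:
    """Steel-Dwass all-pairs nonparametric multiple comparison.

    For each pair of groups the pairwise rank-sum z is computed from the
    pair's own ranks; sqrt(2)·|z| is referred to the studentized-range
    distribution with k groups and infinite degrees of freedom.  The
    family statistic is max sqrt(2)·|z|; the family rejects at ``alpha``
    when any adjusted p falls below it.
    """
    groups = [_clean(g) for g in groups]
    k = len(groups)
    if k < 3:
        raise ValueError(f"need k >= 3 groups, got {k}")
    for i, g in enumerate(groups):
        if g.size < 2:
            raise ValueError(f"group {i} has n < 2")
    comparisons = []
    for i, j in itertools.combinations(range(k), 2):
        z = pairwise_rank_z(groups[i], groups[j])
        q = np.sqrt(2.0) * abs(z)
        p = studentized_range_sf_inf(q, k) if q > 0 else 1.0
        comparisons.append(PairResult((i, j), q, p))
    stat = max(c.statistic for c in comparisons)
    p_family = min(c.p_value for c in comparisons)
    return StatResult(
        "steel_dwass", stat, p_family, tuple(g.size for g in groups),
        "asymptotic", comparisons,
    )


def steel(
    groups,
    control_index: int = 0,
    alpha: float = 0.05,
    n_mc: int = 100_000,
    seed: int = 0,
) -> StatResult:
    """Steel many-to-one comparison of treatments against a control.

    Each treatment's pairwise rank-sum |z| against the control is
    referred to the null distribution of max |Z| over k-1 equicorrelated
    (rho = 0.5) standard normals — the correlation induced by the shared
    control group in a balanced design — integrated by seeded
    Monte-Carlo with ``n_mc`` draws (standard error of an adjusted p
    ~ sqrt(p(1-p)/n_mc)).
    """
    groups = [_clean(g) for g in groups]
    k = len(groups)
    if k < 3:
        raise ValueError(f"need k >= 3 groups, got {k}")
    for i, g in enumerate(groups):
        if g.size < 2:
            raise ValueError(f"group {i} has n < 2")
    if not 0 <= control_index < k:
        raise ValueError("control_index out of range")
    control = groups[control_index]
    zs = []
    pairs = []
    for j in range(k):
        if j == control_index:
            continue
        zs.append(pairwise_rank_z(groups[j], control))
        pairs.append((j, control_index))
    rng = np.random.default_rng(seed)
    x0 = rng.standard_normal(n_mc)
    xi = rng.standard_normal((n_mc, k - 1))
    m = np.max(np.abs((xi + x0[:, None]) / np.sqrt(2.0)), axis=1)
    comparisons = [
        PairResult(pair, abs(z), float(np.mean(m >= abs(z))) if z != 0 else 1.0)
        for pair, z in zip(pairs, zs)
    ]
    stat = max(c.statistic for c in comparisons)
    p_family = min(c.p_value for c in comparisons)
    return StatResult(
        "steel", stat, p_family, tuple(g.size for g in groups),
        "monte_carlo", comparisons,
    )


# ---------------------------------------------------------------------------
# reporting


def results_table(results) -> "pd.DataFrame":
    """Tidy table of test results with significance markers (* p<0.05, ** p<0.01)."""
    import pandas as pd

    rows = []
    for r in results:
        base = {
            "test": r.test_name,
            "method": r.method,
            "n": "/".join(str(v) for v in r.n),
        }
        if r.comparisons:
            for c in r.comparisons:
                rows.append(
                    base
                    | {
                        "comparison": f"{c.pair[0]} vs {c.pair[1]}",
                        "statistic": c.statistic,
                        "p": c.p_value,
                        "significance": _stars(c.p_value),
                    }
                )
        else:
            rows.append(
                base
                | {
                    "comparison": "",
                    "statistic": r.statistic,
                    "p": r.p_value,
                    "significance": _stars(r.p_value),
                }
            )
    return pd.DataFrame(rows)


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
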