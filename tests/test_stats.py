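"""Tests for the nonparametric battery against independent oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from somnophot.stats import (
    friedman,
    kruskal_wallis,
    mann_whitney_u,
    pairwise_rank_z,
    steel,
    steel_dwass,
    studentized_range_crit_inf,
    studentized_range_sf_inf,
    wilcoxon_signed_rank,
)


def wilcoxon_enumeration_oracle(d):
    """Two-sided exact p by explicit loop over all sign assignments."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mu = ranks.sum() / 2.0
    hits = total = 0
    for signs in itertools.product([0, 1], repeat=len(d)):
        w = sum(r for s, r in zip(signs, ranks) if s)
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            hits += 1
    return hits / total


def mannwhitney_enumeration_oracle(a, b):
    pooled = np.concatenate([a, b])
    na = len(a)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:na].sum() - na * (na + 1) / 2.0
    mu = na * len(b) / 2.0
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), na):
        u = ranks[list(idx)].sum() - na * (na + 1) / 2.0
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            hits += 1
    return hits / total


class TestWilcoxon:
    def test_all_positive_n5(self):
        r = wilcoxon_signed_rank([0.3, 1.1, 2.0, 0.7, 5.0])
        assert r.method == "exact"
        assert r.p_value == pytest.approx(0.0625)

    def test_identical_pairs_p1_with_warning(self):
        with pytest.warns(UserWarning, match="zero"):
            r = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.p_value == 1.0

    def test_too_few_nonzero_differences(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([0.0, 0.0, 1.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.normal(0.3, 1.0, size=10)
        r = wilcoxon_signed_rank(d)
        assert r.p_value == pytest.approx(wilcoxon_enumeration_oracle(d), abs=1e-12)

    def test_exact_with_ties_matches_enumeration(self):
        d = np.array([1.0, 1.0, -1.0, 2.0, 2.0, 3.0, -2.0])
        r = wilcoxon_signed_rank(d)
        assert r.p_value == pytest.approx(wilcoxon_enumeration_oracle(d), abs=1e-12)

    def test_two_sidedness_sign_flip_invariance(self):
        d = np.random.default_rng(5).normal(0.5, 1, size=9)
        assert wilcoxon_signed_rank(d).p_value == pytest.approx(
            wilcoxon_signed_rank(-d).p_value
        )

    def test_asymptotic_close_to_exact_at_n_large(self):
        rng = np.random.default_rng(2)
        d = rng.normal(0.4, 1.0, size=15)
        exact = wilcoxon_signed_rank(d).p_value
        # recompute by forcing the asymptotic branch via padding is invasive;
        # instead compare against scipy's normal approximation
        approx = sps.wilcoxon(d, mode="approx", correction=False).pvalue
        assert exact == pytest.approx(approx, abs=0.02)

    def test_pratt_handles_zeros(self):
        d = np.array([0.0, 1.0, 2.0, -1.5, 3.0])
        r = wilcoxon_signed_rank(d, zero_method="pratt")
        assert r.method == "exact"
        assert 0 <= r.p_value <= 1


class TestMannWhitney:
    def test_identical_multisets_p1(self):
        r = mann_whitney_u([1, 2, 2, 3], [1, 2, 2, 3])
        assert r.method == "exact"
        assert r.p_value == 1.0

    def test_complete_separation_3v3(self):
        r = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_matches_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=5), rng.normal(0.8, 1, size=5)
        r = mann_whitney_u(a, b)
        assert r.method == "exact"
        assert r.p_value == pytest.approx(mannwhitney_enumeration_oracle(a, b), abs=1e-12)

    def test_group_swap_invariance(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=6), rng.normal(size=7)
        assert mann_whitney_u(a, b).p_value == pytest.approx(
            mann_whitney_u(b, a).p_value
        )

    def test_shift_monotonicity(self):
        a = np.array([0.1, 0.5, 0.9, 1.4, 2.2])
        b = np.array([0.2, 0.7, 1.1, 1.8, 2.5])
        ps = [mann_whitney_u(a, b + shift).p_value for shift in (0.0, 1.0, 2.0, 4.0)]
        assert all(p2 <= p1 + 1e-12 for p1, p2 in zip(ps, ps[1:]))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestOmnibus:
    def test_friedman_degenerate_identical(self):
        data = np.tile([[1.0, 1.0, 1.0]], (5, 1))
        r = friedman(data)
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_friedman_incomplete_block_named(self):
        data = np.ones((4, 3))
        data[2, 1] = np.nan
        with pytest.raises(ValueError, match="row 2"):
            friedman(data)

    def test_friedman_matches_scipy_without_ties(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(8, 4))
        mine = friedman(data)
        ref = sps.friedmanchisquare(*data.T)
        assert mine.statistic == pytest.approx(ref.statistic)
        assert mine.p_value == pytest.approx(ref.pvalue)

    def test_friedman_exact_never_anticonservative(self):
        # the exact permutation reference is discrete, hence conservative:
        # rejection under the null may fall below but never above 5%
        rng = np.random.default_rng(10)
        n_rep = 1000
        rej = sum(
            friedman(rng.normal(size=(5, 3)), method="exact").p_value < 0.05
            for _ in range(n_rep)
        )
        assert 0.005 <= rej / n_rep <= 0.055

    def test_kruskal_null_calibration(self):
        # 3 groups from one continuous distribution: rejection at alpha=0.05
        rng = np.random.default_rng(21)
        n_rep = 10_000
        rej = sum(
            kruskal_wallis([rng.normal(size=15) for _ in range(3)]).p_value < 0.05
            for _ in range(n_rep)
        )
        assert 0.04 <= rej / n_rep <= 0.06

    def test_kruskal_wallis_k2_equals_mannwhitney_asymptotic(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=20), rng.normal(0.5, 1, size=18)
        kw = kruskal_wallis([a, b])
        mw = mann_whitney_u(a, b)
        assert mw.method == "asymptotic"
        assert kw.p_value == pytest.approx(mw.p_value, abs=1e-6)

    def test_kruskal_identical_degenerate(self):
        r = kruskal_wallis([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])
        assert r.p_value == 1.0


class TestStudentizedRange:
    @pytest.mark.parametrize("q,k", [(2.0, 3), (3.31, 3), (4.5, 5)])
    def test_sf_matches_scipy_large_df(self, q, k):
        assert studentized_range_sf_inf(q, k) == pytest.approx(
            sps.studentized_range.sf(q, k, 1e7), abs=1e-5
        )

    def test_critical_value_inversion(self):
        q = studentized_range_crit_inf(0.05, 3)
        assert studentized_range_sf_inf(q, 3) == pytest.approx(0.05, abs=1e-6)


class TestSteelDwass:
    def test_identical_constant_groups_all_p1(self):
        r = steel_dwass([[1.0, 1.0, 1.0]] * 3)
        assert all(c.p_value == 1.0 for c in r.comparisons)

    def test_group_size_guard(self):
        with pytest.raises(ValueError):
            steel_dwass([[1.0], [1.0, 2.0], [3.0, 4.0]])

    def test_shifted_group_flagged(self):
        rng = np.random.default_rng(12)
        g1, g2 = rng.normal(size=10), rng.normal(size=10)
        g3 = rng.normal(10.0, 1.0, size=10)  # 10-SD shift
        r = steel_dwass([g1, g2, g3])
        pmap = {c.pair: c.p_value for c in r.comparisons}
        assert pmap[(0, 2)] < 0.05 and pmap[(1, 2)] < 0.05
        assert pmap[(0, 1)] > 0.05

    def test_k2_reduction_to_ranksum_z(self):
        # with k=2 "groups" padded by a third far-off group the pairwise z
        # matches the plain rank-sum z; check the building block directly
        rng = np.random.default_rng(13)
        a, b = rng.normal(size=12), rng.normal(0.7, 1, size=12)
        z = pairwise_rank_z(a, b)
        ref = sps.ranksums(a, b).statistic
        assert z == pytest.approx(ref, abs=1e-10)


class TestSteel:
    def test_monte_carlo_matches_mvn_cdf_oracle(self):
        # adjusted p for |z| must equal 1 - P(all |Z_i| < |z|) under the
        # equicorrelated (rho=0.5) MVN; quadrature oracle via scipy mvn
        k = 4
        rho = 0.5
        cov = np.full((k - 1, k - 1), rho) + (1 - rho) * np.eye(k - 1)
        rng = np.random.default_rng(14)
        groups = [rng.normal(size=8) for _ in range(k)]
        res = steel(groups, control_index=0, n_mc=200_000, seed=3)
        mvn = sps.multivariate_normal(mean=np.zeros(k - 1), cov=cov, allow_singular=True)
        for c in res.comparisons:
            z = c.statistic
            lo, hi = -z * np.ones(k - 1), z * np.ones(k - 1)
            p_ref = 1.0 - mvn.cdf(hi, lower_limit=lo)
            assert c.p_value == pytest.approx(p_ref, abs=0.01)

    def test_seeded_determinism(self):
        groups = [[1.0, 2.0, 3.0], [2.0, 3.0, 4.0], [5.0, 6.0, 7.0]]
        r1 = steel(groups, seed=7)
        r2 = steel(groups, seed=7)
        assert [c.p_value for c in r1.comparisons] == [c.p_value for c in r2.comparisons]
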