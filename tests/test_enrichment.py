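"""Enrichment statistics checked against hand arithmetic, exact enumeration,
resampling oracles and an independent library implementation."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import kolmogorov as scipy_kolmogorov

from scmira.enrichment import (
    BGK_BETA,
    NoContrastError,
    bb_test,
    default_cutoff_grid,
    hypergeom_landscape,
    kolmogorov_sup_pvalue,
    mrs_test,
    targetset_ranksum,
)


class TestMrs:
    def test_hand_worked_example(self):
        # N=3, ranks (1,2,3), I=(1,0,0), p=0.1: c=(1,0,-1),
        # T = 0.9 + 0 + 0.1 = 1.0, Var = 2*0.09 = 0.18, Z = 1/sqrt(0.18)
        res = mrs_test([1, 2, 3], [1, 0, 0], [0.1, 0.1, 0.1])
        assert res.statistic == pytest.approx(1.0 / math.sqrt(0.18), abs=1e-9)
        assert res.statistic == pytest.approx(2.357, abs=1e-3)
        assert res.direction == 1

    def test_symmetric_placement_is_null(self):
        # motif genes mirrored around the middle rank with equal p
        ranks = np.arange(1, 8)
        I = [1, 0, 0, 0, 0, 0, 1]
        res = mrs_test(ranks, I, [0.2] * 7)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("indicators", [[1, 1, 1], [0, 0, 0]])
    def test_degenerate_indicators_raise(self, indicators):
        with pytest.raises(NoContrastError):
            mrs_test([1, 2, 3], indicators, [0.1] * 3)

    def test_zero_variance_raises(self):
        with pytest.raises(NoContrastError):
            mrs_test([1, 2, 3], [1, 0, 0], [0.0, 0.0, 0.0])

    def test_normal_pvalue_matches_bernoulli_resampling_oracle(self, rng):
        """The null model is I_g ~ Bernoulli(p_g) at fixed ranks; simulate it."""
        n = 300
        p = rng.uniform(0.05, 0.4, size=n)
        I = (rng.random(n) < p).astype(float)
        if I.min() == I.max():  # pragma: no cover - vanishing probability
            I[0] = 1 - I[0]
        ranks = np.arange(1, n + 1.0)
        res = mrs_test(ranks, I, p)
        c = (n + 1) / 2.0 - ranks
        t_obs = abs(np.sum(c * (I - p)))
        reps = 20_000
        sims = (rng.random((reps, n)) < p).astype(float)
        t_sim = np.abs((sims - p) @ c)
        p_emp = (t_sim >= t_obs).mean()
        assert abs(res.p_value - p_emp) < 0.02

    def test_large_null_prob_downweights_indicator(self):
        """At the same rank, a motif hit in a high-p_g gene adds less to T."""
        ranks = [1, 2, 3, 4]
        base_p = [0.1, 0.1, 0.1, 0.1]
        low = mrs_test(ranks, [1, 0, 0, 0], base_p)
        high = mrs_test(ranks, [1, 0, 0, 0], [0.8, 0.1, 0.1, 0.1])
        assert high.statistic < low.statistic

    def test_naive_ranksum_inflates_when_pg_tracks_rank_but_mrs_calibrated(self, rng):
        """Long-UTR correction: when motif propensity correlates with rank, an
        unweighted rank-sum rejects far too often; mrs stays near nominal."""
        n, reps, alpha = 500, 400, 0.05
        # repressed end has systematically higher motif propensity
        p = np.linspace(0.45, 0.05, n)
        ranks = np.arange(1, n + 1.0)
        mrs_reject = naive_reject = 0
        for _ in range(reps):
            I = (rng.random(n) < p).astype(float)
            if I.min() == I.max():
                continue
            if mrs_test(ranks, I, p).p_value < alpha:
                mrs_reject += 1
            naive = stats.mannwhitneyu(
                ranks[I == 1], ranks[I == 0], alternative="two-sided"
            )
            if naive.pvalue < alpha:
                naive_reject += 1
        assert naive_reject / reps > 0.5
        assert 0.02 <= mrs_reject / reps <= 0.09


class TestKolmogorovSeries:
    def test_boundary_and_tail(self):
        assert kolmogorov_sup_pvalue(0.0) == 1.0
        assert 0.0 < kolmogorov_sup_pvalue(10.0) < 1e-80

    def test_direct_series_value_at_three(self):
        expected = 2 * (math.exp(-18) - math.exp(-72))
        assert kolmogorov_sup_pvalue(3.0) == pytest.approx(expected, rel=1e-12)
        assert kolmogorov_sup_pvalue(3.0) == pytest.approx(3.05e-8, rel=1e-2)

    def test_strictly_decreasing(self):
        vals = [kolmogorov_sup_pvalue(d) for d in (0.5, 1.0, 1.5, 2.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_matches_scipy_special(self):
        for d in (0.4, 0.8, 1.3, 2.1):
            assert kolmogorov_sup_pvalue(d) == pytest.approx(
                float(scipy_kolmogorov(d)), rel=1e-10
            )

    def test_negative_argument_rejected(self):
        with pytest.raises(ValueError):
            kolmogorov_sup_pvalue(-0.1)


class TestBrownianBridge:
    def test_motif_genes_at_top_give_positive_direction(self):
        n = 200
        I = np.zeros(n)
        I[:20] = 1
        p = np.full(n, 0.1)
        res = bb_test(I, p)
        assert res.direction == 1
        assert res.p_value < 0.01

    def test_motif_genes_at_bottom_give_negative_direction(self):
        n = 200
        I = np.zeros(n)
        I[-20:] = 1
        res = bb_test(I, np.full(n, 0.1))
        assert res.direction == -1

    def test_small_n_warns(self):
        with pytest.warns(UserWarning, match="N < 10"):
            bb_test([1, 0, 0, 1, 0], [0.3] * 5)

    def test_zero_variance_raises(self):
        with pytest.warns(UserWarning), pytest.raises(NoContrastError):
            bb_test([1, 0, 0], [0.0, 0.0, 0.0])

    def test_null_pvalues_approximately_uniform(self, rng):
        """Reduced permutation-calibration check (the full-size one runs in
        the acceptance suite)."""
        n, reps = 400, 400
        p = rng.uniform(0.05, 0.3, size=n)
        pvals = []
        for _ in range(reps):
            I = (rng.random(n) < p).astype(float)
            order = rng.permutation(n)
            pvals.append(bb_test(I[order], p[order]).p_value)
        rate = np.mean(np.array(pvals) < 0.05)
        assert 0.02 <= rate <= 0.09
        assert stats.kstest(pvals, "uniform").pvalue > 0.001


def brute_force_hypergeom_upper(N, K, n, k):
    """P(X >= k) for X ~ Hypergeom(N, K, n) by direct enumeration."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
    ) / total


class TestHypergeomLandscape:
    def test_exact_combinatorial_example(self):
        # N=10, K=4, leading n=5 holds k=3: p_over = 66/252
        I = np.array([1, 1, 0, 1, 0, 0, 1, 0, 0, 0], dtype=float)
        res = hypergeom_landscape(I, cutoff_grid=[5])
        assert res.landscape["p_over"][0] == pytest.approx(66 / 252, rel=1e-12)
        assert res.direction == 1

    def test_singleton_grid_equals_plain_two_tail_test(self):
        I = np.array([1, 0, 1, 1, 0, 0, 0, 1, 0, 0, 0, 0], dtype=float)
        n_cut = 4
        res = hypergeom_landscape(I, cutoff_grid=[n_cut])
        N, K = len(I), int(I.sum())
        k = int(I[:n_cut].sum())
        p_over = stats.hypergeom.sf(k - 1, N, K, n_cut)
        p_under = stats.hypergeom.cdf(k, N, K, n_cut)
        assert res.p_value == pytest.approx(min(p_over, p_under), rel=1e-12)

    def test_tails_match_brute_force_enumeration(self):
        for N in (6, 8):
            for K in range(1, N):
                I = np.zeros(N)
                I[:K] = 1
                for n_cut in range(1, N):
                    res = hypergeom_landscape(I, cutoff_grid=[n_cut])
                    k = int(I[:n_cut].sum())
                    assert res.landscape["p_over"][0] == pytest.approx(
                        brute_force_hypergeom_upper(N, K, n_cut, k), abs=1e-12
                    )

    def test_depleted_motif_gives_negative_direction(self):
        I = np.zeros(40)
        I[-15:] = 1  # all motif genes at the up-regulated end
        res = hypergeom_landscape(I)
        assert res.direction == -1

    def test_no_contrast_raises(self):
        with pytest.raises(NoContrastError):
            hypergeom_landscape(np.ones(10))

    def test_default_grid_excludes_full_list(self):
        grid = default_cutoff_grid(100)
        assert grid.max() <= 99 and grid.min() >= 1 and len(grid) == 20

    def test_bonferroni_flag_scales_pvalue(self):
        I = np.array([1, 1, 1, 0, 0, 0, 0, 0, 1, 0], dtype=float)
        plain = hypergeom_landscape(I, cutoff_grid=[3, 5])
        corrected = hypergeom_landscape(I, cutoff_grid=[3, 5], bonferroni=True)
        assert corrected.p_value == pytest.approx(min(1.0, plain.p_value * 2))


class TestTargetsetRanksum:
    def test_extreme_targets_exact_enumeration_oracle(self):
        """Targets at ranks {1,2,3} of 6: exact two-sided p over all C(6,3)
        arrangements is 2/20 = 0.1; the asymptotic test must agree in
        direction and order of magnitude."""
        values = np.array([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0])
        is_target = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        # independent oracle: enumerate every placement of the target set
        ranks = stats.rankdata(values)
        obs = ranks[is_target].sum()
        sums = [
            sum(ranks[list(combo)]) for combo in itertools.combinations(range(6), 3)
        ]
        mean = np.mean(sums)
        p_exact = np.mean([abs(s - mean) >= abs(obs - mean) for s in sums])
        assert p_exact == pytest.approx(0.1)
        res = targetset_ranksum(values, is_target)
        assert res.direction == 1
        assert 0.02 < res.p_value < 0.2

    def test_uniform_under_random_target_choice(self, rng):
        n, reps = 200, 300
        values = rng.normal(size=n)
        pvals = []
        for _ in range(reps):
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, size=50, replace=False)] = True
            pvals.append(targetset_ranksum(values, mask).p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.001

    def test_all_genes_as_targets_raises(self):
        with pytest.raises(NoContrastError):
            targetset_ranksum(np.arange(5.0), np.ones(5, dtype=bool))

    def test_empty_intersection_raises(self):
        with pytest.raises(NoContrastError):
            targetset_ranksum(np.arange(5.0), np.zeros(5, dtype=bool))
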