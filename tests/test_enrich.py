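"""Hypergeometric enrichment, rank/Welch bias tests, compendium meta-analysis."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oscillome import (
    adjusted_rand_index,
    cluster_experiments,
    enrich_categories,
    hypergeom_enrichment,
    meta_rank_sums,
    profile_correlation,
    ranksum_bias,
    welch_bias,
)


def exact_upper_tail(k, N, n, m):
    """P(X >= k) for X ~ Hypergeom(N, n, m) by exact rational summation."""
    total = Fraction(0)
    for i in range(k, min(m, n) + 1):
        total += Fraction(comb(n, i) * comb(N - n, m - i), comb(N, m))
    return float(total)


class TestHypergeom:
    def test_growth_correlation_worked_example(self):
        # 68 of a 414-gene cluster among 240 growth-correlated genes out of
        # 5,795 protein-coding genes
        universe = [f"g{i}" for i in range(5795)]
        cluster = universe[:414]
        category = universe[:68] + universe[414:414 + 172]
        res = hypergeom_enrichment(cluster, category, universe)
        assert (res.N, res.m, res.n, res.k) == (5795, 414, 240, 68)
        assert res.E == pytest.approx((68 / 414) / (240 / 5795), rel=1e-12)
        assert res.E == pytest.approx(3.97, abs=0.01)
        assert res.p == pytest.approx(exact_upper_tail(68, 5795, 240, 414), rel=1e-9)

    def test_zero_overlap(self):
        universe = [f"g{i}" for i in range(100)]
        res = hypergeom_enrichment(universe[:10], universe[50:60], universe)
        assert res.p == 1.0 and res.E == 0.0

    def test_cluster_equals_universe(self):
        universe = [f"g{i}" for i in range(50)]
        res = hypergeom_enrichment(universe, universe[:20], universe)
        assert res.k == res.n == 20
        assert res.p == pytest.approx(1.0)
        assert res.E == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment(["a"], ["a"], [])

    def test_enrichment_sign_iff_frequency_excess(self):
        rng = np.random.default_rng(0)
        universe = [f"g{i}" for i in range(200)]
        for _ in range(50):
            m, n = rng.integers(1, 200, size=2)
            cluster = list(rng.choice(universe, m, replace=False))
            category = list(rng.choice(universe, n, replace=False))
            res = hypergeom_enrichment(cluster, category, universe)
            assert (res.E > 1) == (res.k / res.m > res.n / res.N)

    def test_exhaustive_small_grid_vs_exact_oracle(self):
        for N in range(2, 26):
            for m in range(1, N + 1):
                for n in range(1, N + 1):
                    lo = max(0, m + n - N)
                    for k in range(lo, min(m, n) + 1):
                        p = float(stats.hypergeom.sf(k - 1, N, n, m))
                        assert p == pytest.approx(exact_upper_tail(k, N, n, m),
                                                  rel=1e-9, abs=1e-12), (N, m, n, k)

    def test_sampled_grid_up_to_200_vs_exact_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(400):
            N = int(rng.integers(2, 201))
            m = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            lo = max(0, m + n - N)
            k = int(rng.integers(lo, min(m, n) + 1))
            p = float(stats.hypergeom.sf(k - 1, N, n, m))
            assert p == pytest.approx(exact_upper_tail(k, N, n, m), rel=1e-9, abs=1e-12)


class TestEnrichCategories:
    def test_planted_category_detected(self, labels_7, genome_fixture):
        table = enrich_categories(labels_7, genome_fixture.categories)
        hit = table[(table.cluster == "A") & (table.category == "growth")]
        assert len(hit) == 1 and hit.iloc[0].p < 1e-4
        others = table[(table.category == "growth") & (table.cluster.isin(["C", "D"]))]
        assert (others.p > 1e-4).all()

    def test_disjoint_category_skipped_with_warning(self, labels_7):
        with pytest.warns(UserWarning, match="disjoint"):
            table = enrich_categories(labels_7, {"ghost": {"not_a_gene"}})
        assert table.empty

    def test_permuted_labels_significant_at_alpha_rate(self, labels_7, genome_fixture):
        rng = np.random.default_rng(2)
        rates = []
        for _ in range(20):
            perm = pd.Series(rng.permutation(labels_7.to_numpy()), index=labels_7.index)
            table = enrich_categories(perm, genome_fixture.categories)
            rates.append(np.mean(table.p <= 0.05))
        # upper-tail test at alpha=0.05 is conservative for small categories
        assert np.mean(rates) < 0.10


class TestRanksumBias:
    def test_hand_counted_example(self):
        res = ranksum_bias([1, 3, 5], [2, 4])
        assert res.U == 3
        assert res.r == pytest.approx(0.0)
        assert res.u_frac == pytest.approx(0.5)

    def test_complete_separation(self):
        res = ranksum_bias([10, 11, 12], [1, 2])
        assert res.U == 6 and res.r == pytest.approx(1.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=20), rng.normal(0.5, 1, size=30)
        a, b = ranksum_bias(x, y), ranksum_bias(y, x)
        assert a.r == pytest.approx(-b.r)
        assert a.p == pytest.approx(b.p)

    def test_all_ties_convention(self):
        res = ranksum_bias([2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.p == 1.0 and res.r == 0.0

    def test_exact_p_matches_enumeration(self):
        # m=3, n=2: enumerate all C(5,3)=10 group assignments of ranks
        from itertools import combinations
        x, y = [1.0, 4.0, 5.0], [2.0, 3.0]
        obs = ranksum_bias(x, y)
        us = []
        for pick in combinations(range(5), 3):
            ranks = np.array(pick) + 1
            us.append(ranks.sum() - 3 * 4 / 2)
        us = np.array(us)
        two_sided = np.mean(np.abs(us - 3) >= abs(obs.U - 3))
        assert obs.p == pytest.approx(two_sided)


class TestWelchBias:
    def test_identical_samples(self):
        t, dof, p = welch_bias([1.0, 1.0, 1.0], [1.0, 1.0])
        assert t == 0.0 and p == 1.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=15), rng.normal(1, 2, size=25)
        t1, d1, p1 = welch_bias(x, y)
        t2, d2, p2 = welch_bias(y, x)
        assert t1 == pytest.approx(-t2)
        assert d1 == pytest.approx(d2)
        assert p1 == pytest.approx(p2)

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            x, y = rng.normal(size=12), rng.normal(0.8, 1.7, size=18)
            t, dof, p = welch_bias(x, y)
            oracle = stats.ttest_ind(x, y, equal_var=False)
            assert t == pytest.approx(oracle.statistic, rel=1e-10)
            assert p == pytest.approx(oracle.pvalue, rel=1e-10)


class TestMetaRankSums:
    def test_top_ranked_cluster_reaches_plus_one(self):
        genes = [f"g{i}" for i in range(20)]
        labels = pd.Series(["X"] * 5 + ["Y"] * 15, index=genes)
        comp = pd.DataFrame({"e1": np.arange(20, 0, -1, dtype=float)}, index=genes)
        prof = meta_rank_sums(comp, labels)
        assert prof.r_tilde.loc["X", "e1"] == pytest.approx(1.0)

    def test_planted_blocks_and_anticorrelation(self, labels_7, genome_fixture):
        prof = meta_rank_sums(genome_fixture.compendium, labels_7,
                              clusters=["A", "D"])
        blocks = genome_fixture.truth["compendium_blocks"]
        up_cols = genome_fixture.compendium.columns[:blocks["n_up_experiments"]]
        assert (prof.r_tilde.loc["A", up_cols] > 0).all()
        assert (prof.r_tilde.loc["D", up_cols] < 0).all()
        rho, _ = profile_correlation(prof.r_tilde.loc["A"], prof.r_tilde.loc["D"])
        assert rho < 0

    def test_gene_order_invariance(self, labels_7, genome_fixture):
        comp = genome_fixture.compendium
        shuffled = comp.sample(frac=1.0, random_state=6)
        p1 = meta_rank_sums(comp, labels_7, clusters=["A"])
        p2 = meta_rank_sums(shuffled, labels_7, clusters=["A"])
        assert np.allclose(p1.r_tilde.to_numpy(), p2.r_tilde.to_numpy())

    def test_constant_experiment_is_null(self):
        genes = [f"g{i}" for i in range(10)]
        labels = pd.Series(["X"] * 4 + ["Y"] * 6, index=genes)
        comp = pd.DataFrame({"e1": np.ones(10)}, index=genes)
        prof = meta_rank_sums(comp, labels)
        assert prof.r_tilde.loc["X", "e1"] == 0.0
        assert prof.pvalues.loc["X", "e1"] == 1.0


class TestClusterExperiments:
    def _planted_profiles(self, seed=7, per_group=8):
        rng = np.random.default_rng(seed)
        sigs = np.array([[1, -1, 0, 0.5, -0.5],
                         [-1, 1, 0.5, 0, -0.5],
                         [0, 0, 1, -1, 0.5],
                         [0.5, -0.5, -1, 1, 0],
                         [-0.5, 0.5, 0, -1, 1]])
        cols, truth = {}, []
        for g in range(5):
            for i in range(per_group):
                cols[f"e{g}_{i}"] = sigs[g] + rng.normal(0, 0.05, 5)
                truth.append(g)
        profiles = pd.DataFrame(cols, index=[f"cl{i}" for i in range(5)])
        return profiles, np.array(truth)

    def test_planted_groups_recovered(self):
        profiles, truth = self._planted_profiles()
        clusters, order = cluster_experiments(profiles, K=5, seed=8)
        ari = adjusted_rand_index(truth, clusters.loc[profiles.columns].to_numpy())
        assert ari >= 0.8
        assert sorted(order) == sorted(profiles.columns)

    def test_single_cluster_pure_anchor_ordering(self):
        profiles, _ = self._planted_profiles()
        clusters, order = cluster_experiments(profiles, K=1, seed=9)
        assert clusters.nunique() == 1
        anchor = profiles.loc["cl0", order]
        assert np.all(np.diff(anchor.to_numpy()) <= 1e-12)

    def test_duplicated_columns_colocate(self):
        profiles, _ = self._planted_profiles()
        dup = profiles.copy()
        dup["twin_a"] = profiles.iloc[:, 0]
        dup["twin_b"] = profiles.iloc[:, 0]
        clusters, _ = cluster_experiments(dup, K=5, seed=10)
        assert clusters["twin_a"] == clusters["twin_b"]

    def test_k_larger_than_experiments_rejected(self):
        profiles, _ = self._planted_profiles(per_group=1)
        with pytest.raises(ValueError):
            cluster_experiments(profiles, K=6, seed=11)


class TestProfileCorrelation:
    def test_self_and_negation(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=10)
        assert profile_correlation(x, x)[0] == pytest.approx(1.0)
        assert profile_correlation(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            x, y = rng.normal(size=15), rng.normal(size=15)
            rho, _ = profile_correlation(x, y)
            oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
            assert rho == pytest.approx(oracle, rel=1e-12)

    def test_constant_profile_reported_missing(self):
        with pytest.warns(UserWarning, match="constant"):
            rho, p = profile_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(rho)
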