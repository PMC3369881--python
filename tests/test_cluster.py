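"""t-mixture EM, BIC model selection, circular phase sorting, overlap consensus."""

import numpy as np
import pandas as pd
import pytest

from oscillome import (
    LabelMap,
    adjusted_rand_index,
    boxcox_signed,
    fit_tmixture,
    overlap_consensus,
    phase_density_peak,
    select_K_bic,
    sort_and_relabel,
)
from oscillome.cluster import ClusterAssignment


class TestBoxcoxSigned:
    def test_lambda_one_closed_form(self):
        assert boxcox_signed(3.0, 1.0) == pytest.approx(2.0)
        assert boxcox_signed(-3.0, 1.0) == pytest.approx(-4.0)
        assert boxcox_signed(0.0, 1.0) == pytest.approx(-1.0)

    def test_odd_up_to_constant(self):
        rng = np.random.default_rng(0)
        x = rng.normal(scale=3, size=50)
        for lam in (0.2, 0.7, 1.0, 1.8):
            assert np.allclose(boxcox_signed(-x, lam) + boxcox_signed(x, lam),
                               -2.0 / lam)

    @pytest.mark.parametrize("lam", [0.1, 0.5, 1.0, 2.0])
    def test_strictly_monotone_on_random_grid(self, lam):
        rng = np.random.default_rng(1)
        grid = np.sort(rng.uniform(-50, 50, size=400))
        assert np.all(np.diff(boxcox_signed(grid, lam)) > 0)

    def test_lambda_outside_search_box_rejected(self):
        with pytest.raises(ValueError):
            boxcox_signed(1.0, 0.0)
        with pytest.raises(ValueError):
            boxcox_signed(1.0, 2.5)


class TestTMixtureEM:
    def test_single_component_recovers_mean(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(500, 2))
        model, assign = fit_tmixture(x, K=1, lam=1.0, seed=3, restarts=2)
        assert np.all(np.abs(model.means[0] - x.mean(axis=0)) < 0.15)

    def test_separated_blobs_fully_recovered(self):
        rng = np.random.default_rng(3)
        x = np.vstack([rng.normal([-5, 0], 0.5, (200, 2)),
                       rng.normal([5, 0], 0.5, (200, 2))])
        truth = np.repeat([0, 1], 200)
        model, assign = fit_tmixture(x, K=2, lam=1.0, seed=4, restarts=3)
        assert adjusted_rand_index(truth, assign.labels.to_numpy()) == 1.0

    def test_loglik_monotone_nondecreasing(self):
        rng = np.random.default_rng(4)
        x = np.vstack([rng.standard_t(4, (300, 2)) + [-3, 0],
                       rng.standard_t(4, (300, 2)) + [3, 0]])
        for lam in (1.0, None):
            model, _ = fit_tmixture(x, K=2, lam=lam, seed=5, restarts=2)
            diffs = np.diff(model.loglik_trace)
            assert np.all(diffs >= -1e-8 * np.abs(model.loglik_trace[:-1]))

    def test_t_mixture_weight_recovery(self):
        # data truly from a 2-component bivariate t (nu=4), several seeds
        ok = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n1 = 1400
            w = np.sqrt(4 / rng.chisquare(4, size=2000))
            centers = np.vstack([np.tile([-4.0, 0.0], (n1, 1)),
                                 np.tile([4.0, 0.0], (2000 - n1, 1))])
            x = centers + rng.normal(size=(2000, 2)) * w[:, None]
            model, _ = fit_tmixture(x, K=2, nu=4, lam=1.0, seed=seed, restarts=3)
            w_big = max(model.weights)
            if abs(w_big - 0.7) <= 0.05:
                ok += 1
        assert ok >= 9

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(6)
        model, assign = fit_tmixture(rng.normal(size=(200, 2)), K=2, lam=1.0,
                                     seed=7, restarts=2)
        assert np.allclose(assign.posteriors.sum(axis=1), 1.0)
        assert np.isclose(model.weights.sum(), 1.0)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_tmixture(np.zeros((15, 2)), K=2)       # n < 10K
        bad = np.ones((40, 2)); bad[0, 0] = np.inf
        with pytest.raises(ValueError):
            fit_tmixture(bad, K=2)


class TestSelectKBic:
    def test_three_blobs_selects_three(self):
        chosen = []
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            x = np.vstack([rng.normal(c, 0.4, (120, 2))
                           for c in ([-5, 0], [5, 0], [0, 6])])
            best, _ = select_K_bic(x, [1, 2, 3, 4], lam=1.0, seed=seed, restarts=3)
            chosen.append(best)
        assert sum(k == 3 for k in chosen) >= 9

    def test_single_blob_selects_one(self):
        chosen = []
        for seed in range(10):
            rng = np.random.default_rng(300 + seed)
            x = rng.normal(size=(300, 2))
            best, _ = select_K_bic(x, [1, 2, 3], lam=1.0, seed=seed, restarts=3)
            chosen.append(best)
        assert sum(k == 1 for k in chosen) >= 9

    def test_singleton_range(self):
        rng = np.random.default_rng(8)
        best, fits = select_K_bic(rng.normal(size=(100, 2)), [2], lam=1.0,
                                  seed=9, restarts=2)
        assert best == 2 and set(fits) == {2}

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            select_K_bic(np.zeros((50, 2)), [])


class TestPhaseDensityPeak:
    def test_point_mass(self):
        assert phase_density_peak([123.0] * 5) == pytest.approx(123.0)

    def test_wraparound_mode_near_zero(self):
        phases = np.arange(350.0, 371.0) % 360.0      # 350..359, 0..10
        peak = phase_density_peak(phases)
        assert min(peak, 360 - peak) <= 5

    def test_von_mises_sample_mode(self):
        rng = np.random.default_rng(9)
        sample = np.rad2deg(rng.vonmises(np.deg2rad(90), 5, size=1000)) % 360
        assert phase_density_peak(sample) == pytest.approx(90, abs=10)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            phase_density_peak([10.0, 20.0])


def _assignment(labels, genes=None):
    labels = pd.Series(labels, index=genes or [f"g{i}" for i in range(len(labels))])
    post = pd.get_dummies(labels).astype(float)
    return ClusterAssignment(labels=labels, posteriors=post)


class TestSortAndRelabel:
    def test_hand_enumerated_three_cluster_order(self):
        # peaks at 200, 80 and 320 degrees; anchor = the 80-degree cluster
        labels = ["x"] * 5 + ["y"] * 5 + ["z"] * 5
        phases = pd.Series([200.0] * 5 + [80.0] * 5 + [320.0] * 5,
                           index=[f"g{i}" for i in range(15)])
        out = sort_and_relabel(_assignment(labels), phases, anchor_label="y")
        # shifted peaks: y -> 1, z -> 241, x -> 121  => order y, x, z
        assert out.labels[phases.index[5]] == "A"     # the anchor (80 deg)
        assert out.labels[phases.index[0]] == "B"     # 200 deg
        assert out.labels[phases.index[10]] == "C"    # 320 deg
        assert out.peaks["A"] == pytest.approx(1.0)

    def test_single_cluster_identity(self):
        phases = pd.Series([10.0] * 8, index=[f"g{i}" for i in range(8)])
        out = sort_and_relabel(_assignment(["u"] * 8), phases, anchor_label="u")
        assert (out.labels == "A").all()

    def test_global_phase_rotation_preserves_order(self):
        rng = np.random.default_rng(10)
        labels = ["a"] * 20 + ["b"] * 20 + ["c"] * 20
        base = np.concatenate([rng.normal(40, 5, 20), rng.normal(160, 5, 20),
                               rng.normal(280, 5, 20)])
        genes = [f"g{i}" for i in range(60)]
        out1 = sort_and_relabel(_assignment(labels), pd.Series(base, index=genes), "a")
        out2 = sort_and_relabel(_assignment(labels),
                                pd.Series((base + 77) % 360, index=genes), "a")
        assert (out1.labels == out2.labels).all()

    def test_unknown_anchor_rejected(self):
        phases = pd.Series([1.0] * 6, index=[f"g{i}" for i in range(6)])
        with pytest.raises(ValueError):
            sort_and_relabel(_assignment(["a"] * 6), phases, anchor_label="zz")


class TestOverlapConsensus:
    def _labels(self, spec):
        # spec: list of (labelA, labelB, count)
        genes, la, lb = [], [], []
        i = 0
        for a, b, cnt in spec:
            for _ in range(cnt):
                genes.append(f"g{i}"); la.append(a); lb.append(b); i += 1
        idx = pd.Index(genes)
        return pd.Series(la, index=idx), pd.Series(lb, index=idx)

    def test_identical_clusterings_diagonal(self):
        la, lb = self._labels([("A", "A", 30), ("B", "B", 30), ("C", "C", 30)])
        lmap = LabelMap(cells={("A", "A"): "A", ("B", "B"): "B", ("C", "C"): "C"})
        res = overlap_consensus(la, lb, lmap, p_threshold=0.05)
        for i in "ABC":
            for j in "ABC":
                if i == j:
                    assert res.pvalues.loc[i, j] < 1e-10
                else:
                    assert res.counts.loc[i, j] == 0
                    assert res.pvalues.loc[i, j] == 1.0
        assert (res.consensus.loc[la.index] == la).all()

    def test_planted_pairwise_design_recovered_exactly(self):
        # every consensus cohort is its own contingency cell, strongly
        # enriched against the independence null
        la, lb = self._labels([("A", "a1", 40), ("A", "a2", 25), ("B", "b1", 40),
                               ("B", "b2", 25), ("C", "c", 40)])
        lmap = LabelMap(cells={("A", "a1"): "A", ("A", "a2"): "AB",
                               ("B", "b1"): "B", ("B", "b2"): "B.C",
                               ("C", "c"): "C"})
        res = overlap_consensus(la, lb, lmap, p_threshold=1e-3)
        expected = pd.Series(
            ["A"] * 40 + ["AB"] * 25 + ["B"] * 40 + ["B.C"] * 25 + ["C"] * 40,
            index=la.index)
        assert (res.consensus.loc[la.index] == expected).all()

    def test_zero_threshold_gives_all_background(self):
        la, lb = self._labels([("A", "A", 50), ("B", "B", 50)])
        lmap = LabelMap(cells={("A", "A"): "A", ("B", "B"): "B"},
                        fallback={"B": "l.b"})
        res = overlap_consensus(la, lb, lmap, p_threshold=0.0)
        assert set(res.consensus[la.index[la == "A"]]) == {"n"}
        assert set(res.consensus[la.index[la == "B"]]) == {"l.b"}

    def test_absent_genes_labeled_r(self):
        la, lb = self._labels([("A", "A", 50)])
        lmap = LabelMap(cells={("A", "A"): "A"})
        universe = la.index.append(pd.Index(["missing1", "missing2"]))
        res = overlap_consensus(la, lb, lmap, universe=universe)
        assert res.consensus["missing1"] == "r"

    def test_unknown_map_cell_rejected(self):
        la, lb = self._labels([("A", "A", 50)])
        with pytest.raises(ValueError):
            overlap_consensus(la, lb, LabelMap(cells={("A", "Q"): "AQ"}))
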