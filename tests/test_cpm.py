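"""Connectome-based predictive modeling: selection, CV, stability."""

import numpy as np
import pytest

from dynafc import cpm
from dynafc.connectivity import n_edges


def planted_features(seed, n=20, p=200, n_informative=5, r2=0.6):
    """Edge table where a few edges share a latent signal driving behavior."""
    rng = np.random.default_rng(seed)
    latent = rng.standard_normal(n)
    x = rng.standard_normal((n, p))
    x[:, :n_informative] = latent[:, None] + 0.3 * rng.standard_normal(
        (n, n_informative))
    noise_var = (1 - r2) / r2
    y = latent + np.sqrt(noise_var) * rng.standard_normal(n)
    return x, y


class TestSelectEdges:
    def test_vacuous_threshold_selects_everything(self, rng):
        x = rng.standard_normal((10, 30))
        y = rng.standard_normal(10)
        pos, neg = cpm.select_edges(x, y, 1.0)
        assert len(pos) + len(neg) == 30
        assert np.intersect1d(pos, neg).size == 0

    def test_planted_edge_lands_in_positive_set(self, rng):
        y = rng.standard_normal(20)
        x = rng.standard_normal((20, 50))
        x[:, 0] = y + 0.1 * rng.standard_normal(20)
        pos, neg = cpm.select_edges(x, y, 0.01)
        assert 0 in pos and 0 not in neg

    def test_null_selection_rate_matches_binomial(self):
        """~1% of 1000 null edges selected at p < 0.01, across seeds."""
        total = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal((20, 1000))
            y = rng.standard_normal(20)
            pos, neg = cpm.select_edges(x, y, 0.01)
            total += len(pos) + len(neg)
        expected = 0.01 * 1000 * n_seeds
        # 95% binomial interval around 100 of 10000
        assert abs(total - expected) < 2 * np.sqrt(expected)

    def test_constant_behavior_rejected(self, rng):
        with pytest.raises(ValueError, match="constant behavior"):
            cpm.select_edges(rng.standard_normal((8, 5)), np.ones(8), 0.05)

    def test_constant_edge_skipped_with_warning(self, rng):
        x = rng.standard_normal((10, 5))
        x[:, 2] = 7.0
        with pytest.warns(UserWarning, match="constant edge"):
            pos, neg = cpm.select_edges(x, rng.standard_normal(10), 1.0)
        assert 2 not in pos and 2 not in neg


class TestSummarizeFeatures:
    def test_empty_sets_give_zero(self):
        assert cpm.summarize_features(np.array([1.0, 2.0]), [], []) == 0.0

    def test_signed_difference(self):
        row = np.array([2.0, 0.5, 9.0])
        assert cpm.summarize_features(row, [0], [1]) == pytest.approx(1.5)

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            cpm.summarize_features(np.array([1.0, 2.0]), [0], [0, 1])


class TestLoocv:
    def test_each_participant_held_out_once(self, rng):
        x = rng.standard_normal((12, 40))
        y = rng.standard_normal(12)
        res = cpm.cpm_loocv(None, x, y, cpm.CpmConfig(feature_space="dfc"),
                            p_thresh=0.5)
        assert res.predictions.shape == (12,)
        assert len(res.fold_edges) == 12

    def test_planted_signal_recovered(self):
        x, y = planted_features(seed=0)
        res = cpm.cpm_loocv(None, x, y, cpm.CpmConfig(feature_space="dfc"),
                            p_thresh=0.01)
        assert res.performance_r is not None and res.performance_r > 0.5

    def test_no_leakage_fold_models_reproducible(self):
        """Refitting any fold on the reduced data reproduces the stored
        selection exactly."""
        x, y = planted_features(seed=3)
        res = cpm.cpm_loocv(None, x, y, cpm.CpmConfig(feature_space="dfc"),
                            p_thresh=0.05)
        for i, (pos, neg) in enumerate(res.fold_edges):
            keep = np.arange(len(y)) != i
            pos2, neg2 = cpm.select_edges(x[keep], y[keep], 0.05)
            np.testing.assert_array_equal(pos, pos2)
            np.testing.assert_array_equal(neg, neg2)

    def test_zero_edge_folds_predict_training_mean(self, rng):
        x = rng.standard_normal((10, 20))
        y = rng.standard_normal(10)
        res = cpm.cpm_loocv(None, x, y, cpm.CpmConfig(feature_space="dfc"),
                            p_thresh=1e-6)
        assert len(res.flagged_folds) == 10
        for i in range(10):
            assert res.predictions[i] == pytest.approx(
                y[np.arange(10) != i].mean())

    def test_relaxing_threshold_never_drops_edges_within_fold(self):
        x, y = planted_features(seed=5)
        strict = cpm.cpm_loocv(None, x, y, cpm.CpmConfig(feature_space="dfc"),
                               p_thresh=0.01)
        loose = cpm.cpm_loocv(None, x, y, cpm.CpmConfig(feature_space="dfc"),
                              p_thresh=0.05)
        for (ps, ns), (pl, nl) in zip(strict.fold_edges, loose.fold_edges):
            assert set(ps) <= set(pl)
            assert set(ns) <= set(nl)

    def test_too_few_participants_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 5"):
            cpm.cpm_loocv(None, rng.standard_normal((4, 5)),
                          rng.standard_normal(4),
                          cpm.CpmConfig(feature_space="dfc"))

    def test_determinism(self):
        x, y = planted_features(seed=9)
        cfg = cpm.CpmConfig(feature_space="dfc")
        a = cpm.cpm_loocv(None, x, y, cfg, p_thresh=0.03)
        b = cpm.cpm_loocv(None, x, y, cfg, p_thresh=0.03)
        np.testing.assert_array_equal(a.predictions, b.predictions)
        assert a.performance_r == b.performance_r

    def test_two_predictor_variant_runs(self):
        x, y = planted_features(seed=2)
        res = cpm.cpm_loocv(None, x, y,
                            cpm.CpmConfig(feature_space="dfc",
                                          combine="two-predictor"),
                            p_thresh=0.01)
        assert res.performance_r is not None and res.performance_r > 0.3


class TestThresholdSweep:
    def test_curve_shape_and_declared_best(self):
        x, y = planted_features(seed=1)
        cfg = cpm.CpmConfig(p_thresholds=(0.01, 0.05), feature_space="dfc")
        res = cpm.threshold_sweep(None, x, y, cfg)
        assert len(res.per_threshold) == 2
        assert res.best_threshold in (0.01, 0.05)
        curve = res.performance_curve()
        assert list(curve.columns) == ["p_thresh", "r", "n_flagged_folds"]

    def test_strong_signal_is_robust_across_grid(self):
        x, y = planted_features(seed=4, r2=0.7)
        res = cpm.threshold_sweep(None, x, y,
                                  cpm.CpmConfig(feature_space="dfc"))
        rs = [tr.performance_r for tr in res.per_threshold.values()
              if tr.performance_r is not None]
        assert max(rs) - min(rs) < 0.2

    def test_ties_break_toward_stricter_threshold(self):
        x, y = planted_features(seed=8)
        cfg = cpm.CpmConfig(p_thresholds=(0.04, 0.05), feature_space="dfc")
        res = cpm.threshold_sweep(None, x, y, cfg)
        rs = {p: t.performance_r for p, t in res.per_threshold.items()}
        if rs[0.04] == rs[0.05]:
            assert res.best_threshold == 0.04


class TestStability:
    def test_always_selected_edge_included(self):
        x, y = planted_features(seed=0)
        cfg = cpm.CpmConfig(feature_space="dfc")
        res = cpm.threshold_sweep(None, x, y, cfg)
        stable = cpm.stable_edges(res, res.best)
        assert (stable["frequency"] >= 0.75).all()
        assert len(stable) >= 1

    def test_070_frequency_excluded_at_075(self):
        x, y = planted_features(seed=0)
        cfg = cpm.CpmConfig(feature_space="dfc")
        res = cpm.threshold_sweep(None, x, y, cfg)
        tr = res.best
        tr.selection_frequency[:] = 0.0
        tr.selection_frequency[0] = 14 / 20
        assert len(cpm.stable_edges(res, tr)) == 0

    def test_frequency_matches_brute_force_recount(self):
        x, y = planted_features(seed=6)
        res = cpm.cpm_loocv(None, x, y, cpm.CpmConfig(feature_space="dfc"),
                            p_thresh=0.05)
        counts = np.zeros(x.shape[1])
        for pos, neg in res.fold_edges:
            for e in list(pos) + list(neg):
                counts[e] += 1
        np.testing.assert_allclose(res.selection_frequency,
                                   counts / len(y))


class TestNodeSubset:
    def test_single_node_star(self, rng):
        table = rng.standard_normal((5, n_edges(89)))
        sub, keep = cpm.node_subset_features(table, [0], 89)
        assert sub.shape[1] == 88

    def test_two_node_inclusion_exclusion(self, rng):
        table = rng.standard_normal((5, n_edges(89)))
        sub, _ = cpm.node_subset_features(table, [0, 1], 89)
        assert sub.shape[1] == 2 * 88 - 1 == 175

    def test_full_subset_keeps_all_3916(self, rng):
        table = rng.standard_normal((5, n_edges(89)))
        sub, _ = cpm.node_subset_features(table, list(range(89)), 89)
        assert sub.shape[1] == 3916

    def test_empty_subset_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            cpm.node_subset_features(rng.standard_normal((5, 3)), [], 3)


class TestSignReversal:
    def _result_pair(self, flip, seed=0):
        """Two sweeps over the same features: behavior vs its (possibly
        sign-flipped) twin, producing known correlation signs."""
        x, y = planted_features(seed=seed)
        cfg = cpm.CpmConfig(feature_space="dfc")
        res_a = cpm.threshold_sweep(None, x, y, cfg)
        res_b = cpm.threshold_sweep(None, x, -y if flip else y, cfg)
        return res_a, res_b

    def test_identical_behaviors_show_no_reversals(self):
        res_a, res_b = self._result_pair(flip=False)
        rep = cpm.sign_reversal_report(res_a, res_b)
        assert rep["n_common"] > 0
        assert rep["n_reversed"] == 0

    def test_negated_behavior_reverses_every_common_edge(self):
        res_a, res_b = self._result_pair(flip=True)
        rep = cpm.sign_reversal_report(res_a, res_b)
        assert rep["n_common"] > 0
        assert rep["n_reversed"] == rep["n_common"]

    def test_disjoint_stable_sets_give_empty_report_with_note(self, rng):
        x1, y1 = planted_features(seed=1)
        cfg = cpm.CpmConfig(feature_space="dfc")
        res_a = cpm.threshold_sweep(None, x1, y1, cfg)
        # independent null features: no shared stable edges expected
        x2 = rng.standard_normal(x1.shape)
        res_b = cpm.threshold_sweep(None, x2, rng.standard_normal(len(y1)),
                                    cfg)
        rep = cpm.sign_reversal_report(res_a, res_b)
        if rep["n_common"] == 0:
            assert rep["note"]
            assert len(rep["edges"]) == 0
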