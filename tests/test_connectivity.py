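"""sFC, GARCH/DCC estimation and edge bookkeeping.

The likelihood oracles here are deliberately naive: explicit Python loops
replaying the variance and pseudo-correlation recursions, independent of
the vectorized filter implementation they check.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dynafc import connectivity as conn
from dynafc import synthetic as syn


def garch_loglik_replay(eps, omega, alpha, beta):
    """Straight-loop Gaussian log-likelihood of a GARCH(1,1) fit."""
    t = len(eps)
    sigma2 = [np.var(eps)]
    for i in range(1, t):
        sigma2.append(omega + alpha * eps[i - 1] ** 2 + beta * sigma2[i - 1])
    ll = 0.0
    for i in range(t):
        ll -= 0.5 * (np.log(2 * np.pi) + np.log(sigma2[i])
                     + eps[i] ** 2 / sigma2[i])
    return ll, np.array(sigma2)


def dcc_loglik_replay(z1, z2, a, b, s_bar):
    """Straight-loop stage-2 DCC quasi log-likelihood."""
    t = len(z1)
    q11 = q22 = 1.0
    q12 = s_bar
    ll = 0.0
    rho_path = []
    for i in range(t):
        rho = q12 / np.sqrt(q11 * q22)
        rho = min(max(rho, -0.999999), 0.999999)
        rho_path.append(rho)
        om = 1.0 - rho ** 2
        ll -= 0.5 * (np.log(om)
                     + (z1[i] ** 2 + z2[i] ** 2 - 2 * rho * z1[i] * z2[i]) / om
                     - z1[i] ** 2 - z2[i] ** 2)
        q11 = (1 - a - b) + a * z1[i] ** 2 + b * q11
        q22 = (1 - a - b) + a * z2[i] ** 2 + b * q22
        q12 = (1 - a - b) * s_bar + a * z1[i] * z2[i] + b * q12
    return ll, np.array(rho_path)


class TestEdgeVectorization:
    def test_89_nodes_give_3916_edges(self):
        assert conn.n_edges(89) == 3916
        assert conn.edge_vectorize(np.zeros((89, 89))).size == 3916

    def test_canonical_order_for_three_nodes(self):
        m = np.array([[0., 1, 2], [1, 0, 3], [2, 3, 0]])
        np.testing.assert_array_equal(conn.edge_vectorize(m), [1, 2, 3])

    def test_edge_index_matches_vector_position(self):
        n = 10
        m = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        m[iu] = np.arange(len(iu[0]))
        m = m + m.T
        vec = conn.edge_vectorize(m)
        for pos, (i, j) in enumerate(zip(*iu)):
            assert conn.edge_index(int(i), int(j), n) == pos
            assert conn.edge_index(int(j), int(i), n) == pos
            assert conn.edge_nodes(pos, n) == (i, j)
            assert vec[pos] == m[i, j]

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(min_value=2, max_value=12), st.integers(0, 2 ** 31 - 1))
    def test_roundtrip_is_lossless(self, n, seed):
        r = np.random.default_rng(seed).standard_normal((n, n))
        m = (r + r.T) / 2
        np.fill_diagonal(m, 0.0)
        back = conn.edge_devectorize(conn.edge_vectorize(m), n)
        off = ~np.eye(n, dtype=bool)
        np.testing.assert_allclose(back[off], m[off])

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            conn.edge_vectorize(np.zeros((3, 4)))


class TestStaticFc:
    def test_null_correlation_near_zero(self, rng):
        y = rng.standard_normal((5000, 2))
        z = conn.static_fc(y).values[0, 1]
        assert abs(z) < 3.0 / np.sqrt(5000 - 3)

    def test_fisher_z_of_known_correlation(self, rng):
        rho = 0.5
        x = rng.standard_normal(5000)
        y = rho * x + np.sqrt(1 - rho ** 2) * rng.standard_normal(5000)
        z = conn.static_fc(np.column_stack([x, y])).values[0, 1]
        assert abs(z - np.arctanh(rho)) < 3.0 / np.sqrt(5000 - 3)

    def test_duplicated_column_capped_with_warning(self, rng):
        x = rng.standard_normal(200)
        with pytest.warns(UserWarning, match="capped"):
            m = conn.static_fc(np.column_stack([x, x]))
        assert m.values[0, 1] == pytest.approx(np.arctanh(0.999999))

    def test_constant_column_names_node(self, rng):
        y = rng.standard_normal((50, 2))
        y[:, 1] = 2.0
        with pytest.raises(ValueError, match="flat"):
            conn.static_fc(y, node_labels=["good", "flat"])

    def test_permutation_equivariance(self, rng):
        y = rng.standard_normal((100, 5))
        perm = rng.permutation(5)
        a = conn.static_fc(y).values
        b = conn.static_fc(y[:, perm]).values
        np.testing.assert_allclose(a[np.ix_(perm, perm)], b, atol=1e-12,
                                   equal_nan=True)


class TestGarchFit:
    def test_loglik_matches_straight_loop_replay(self, garch_default):
        series, _ = syn.simulate_garch_series(garch_default, 800, seed=4)
        fit = conn.garch11_fit(series)
        eps = series - series.mean()
        replay_ll, replay_s2 = garch_loglik_replay(eps, fit.omega, fit.alpha,
                                                   fit.beta)
        assert abs(fit.loglik - replay_ll) < 1e-6
        np.testing.assert_allclose(fit.sigma2, replay_s2, atol=1e-10)

    def test_standardized_residuals_are_standardized(self, garch_default):
        series, _ = syn.simulate_garch_series(garch_default, 2000, seed=5)
        fit = conn.garch11_fit(series)
        assert fit.converged
        assert abs(fit.std_resid.mean()) < 0.1
        assert abs(fit.std_resid.var() - 1.0) < 0.1

    def test_parameter_recovery(self, garch_default):
        """Median estimates across replicates approach the truth."""
        alphas, betas = [], []
        for seed in range(15):
            series, _ = syn.simulate_garch_series(garch_default, 2000, seed)
            fit = conn.garch11_fit(series)
            alphas.append(fit.alpha)
            betas.append(fit.beta)
        assert abs(np.median(alphas) - garch_default.alpha) < 0.05
        assert abs(np.median(betas) - garch_default.beta) < 0.10

    def test_white_noise_fits_near_constant_variance(self, rng):
        sums = [conn.garch11_fit(rng.standard_normal(2000)).alpha
                + conn.garch11_fit(rng.standard_normal(2000)).beta
                for _ in range(5)]
        assert np.median(sums) < 0.2

    def test_loglik_never_below_constant_variance_fallback(self, rng):
        from dynafc.connectivity import _garch_nll
        y = rng.standard_normal(300)
        fit = conn.garch11_fit(y)
        eps = y - y.mean()
        fallback_ll = -_garch_nll(np.array([eps.var(), 0.0, 0.0]), eps)
        assert fit.loglik >= fallback_ll - 1e-9

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            conn.garch11_fit(np.ones(300))

    def test_short_series_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 100"):
            conn.garch11_fit(rng.standard_normal(50))


class TestDccFit:
    def _std_resid_pair(self, dcc_params, seed, t=2000):
        pair, rho = syn.simulate_dcc_edge(syn.GarchParams(), syn.GarchParams(),
                                          dcc_params, t, seed)
        z1 = conn.garch11_fit(pair[:, 0]).std_resid
        z2 = conn.garch11_fit(pair[:, 1]).std_resid
        return z1, z2, rho

    def test_loglik_matches_straight_loop_replay(self, dcc_dynamic):
        z1, z2, _ = self._std_resid_pair(dcc_dynamic, seed=1, t=600)
        fit = conn.dcc_fit_edge(z1, z2)
        replay_ll, replay_rho = dcc_loglik_replay(z1, z2, fit.a, fit.b,
                                                  fit.s_bar)
        assert abs(fit.loglik - replay_ll) < 1e-6
        np.testing.assert_allclose(fit.rho, replay_rho, atol=1e-10)

    def test_persistence_recovery(self, dcc_dynamic):
        sums = []
        for seed in range(10):
            z1, z2, _ = self._std_resid_pair(dcc_dynamic, seed)
            fit = conn.dcc_fit_edge(z1, z2)
            sums.append(fit.a + fit.b)
        assert abs(np.median(sums) - 0.95) < 0.15

    def test_constant_correlation_orders_below_dynamic(self, dcc_dynamic,
                                                       dcc_constant):
        """Fitted path variance separates null from dynamic edges."""
        wins = 0
        n_pairs = 20
        for seed in range(n_pairs):
            z1, z2, _ = self._std_resid_pair(dcc_constant, seed, t=1000)
            v_null = np.var(conn.dcc_fit_edge(z1, z2).rho, ddof=1)
            z1, z2, _ = self._std_resid_pair(dcc_dynamic, seed, t=1000)
            v_dyn = np.var(conn.dcc_fit_edge(z1, z2).rho, ddof=1)
            wins += v_null < v_dyn
        assert wins >= 0.9 * n_pairs

    def test_identical_residuals_marked_degenerate(self, rng):
        z = rng.standard_normal(300)
        fit = conn.dcc_fit_edge(z, z)
        assert fit.degenerate
        assert fit.dfc_variance == 0.0
        assert np.ptp(fit.rho) == 0.0

    def test_mismatched_lengths_rejected(self, rng):
        with pytest.raises(ValueError, match="lengths"):
            conn.dcc_fit_edge(rng.standard_normal(200),
                              rng.standard_normal(300))


class TestDynamicFc:
    def test_matrix_symmetric_nonnegative(self, rng):
        y = rng.standard_normal((200, 4))
        mat, qc = conn.dynamic_fc(y)
        off = ~np.eye(4, dtype=bool)
        assert np.all(mat.values[off] >= 0)
        np.testing.assert_allclose(mat.values, mat.values.T, equal_nan=True)
        assert len(qc) == 6

    def test_duplicated_node_recorded_degenerate_in_qc(self, rng):
        y = rng.standard_normal((200, 3))
        y = np.column_stack([y, y[:, 0]])
        mat, qc = conn.dynamic_fc(y)
        flagged = qc[qc.degenerate]
        assert {("n0", "n3")} == set(zip(flagged.node_i, flagged.node_j))
        assert mat.values[0, 3] == 0.0

    def test_permutation_equivariance(self, rng):
        y = rng.standard_normal((150, 4))
        perm = np.array([2, 0, 3, 1])
        a, _ = conn.dynamic_fc(y)
        b, _ = conn.dynamic_fc(y[:, perm])
        np.testing.assert_allclose(a.values[np.ix_(perm, perm)], b.values,
                                   atol=1e-10, equal_nan=True)

    def test_longer_scans_do_not_worsen_recovery(self, dcc_dynamic):
        """Monotone information: quadrupling T does not increase the median
        absolute error of the recovered GARCH and DCC parameters."""
        garch_err, dcc_err = {}, {}
        for t in (250, 1000):
            eg, ed = [], []
            for seed in range(16):
                pair, _ = syn.simulate_dcc_edge(syn.GarchParams(),
                                                syn.GarchParams(),
                                                dcc_dynamic, t, seed)
                f1 = conn.garch11_fit(pair[:, 0])
                f2 = conn.garch11_fit(pair[:, 1])
                eg.append(abs(f1.alpha - 0.10) + abs(f1.beta - 0.85))
                fit = conn.dcc_fit_edge(f1.std_resid, f2.std_resid)
                ed.append(abs((fit.a + fit.b) - 0.95))
            garch_err[t] = np.median(eg)
            dcc_err[t] = np.median(ed)
        assert garch_err[1000] <= garch_err[250]
        assert dcc_err[1000] <= dcc_err[250]
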