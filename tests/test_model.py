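import numpy as np
import pytest

import tvpfavar as tf
from tvpfavar.model import (
    FilterConfig,
    ewma_update,
    initialize,
    kalman_update,
    predict,
    smooth_gaussian_paths,
)

from conftest import kalman_rts_oracle, rls_posterior


class TestInitialize:
    def test_identity_initial_covariances(self):
        cfg = FilterConfig(lags=2)
        st = initialize(cfg, n=5, l=2)
        np.testing.assert_array_equal(st.V, np.ones(5))  # V_0 = 1 x I_n
        np.testing.assert_array_equal(st.Q, np.eye(3))  # Q_0 = 1 x I_{l+1}
        assert st.lam.shape == (5, 3)
        assert st.beta.shape == (7 * 3,)

    def test_degenerate_prior_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            initialize(FilterConfig(init_state_variance=0.0), n=2, l=1)


class TestPredict:
    def test_forgetting_one_is_identity_with_zero_innovation(self):
        cfg = FilterConfig(k3=1.0, k4=1.0)
        st = initialize(cfg, n=3, l=1)
        pred, w_max, r_max = predict(st, cfg)
        assert w_max == 0.0 and r_max == 0.0
        np.testing.assert_array_equal(pred.Sig_lam, st.Sig_lam)
        np.testing.assert_array_equal(pred.Sig_beta, st.Sig_beta)

    def test_scalar_inflation(self):
        cfg = FilterConfig(k3=0.99, k4=0.98, init_state_variance=1.0)
        st = initialize(cfg, n=2, l=1)
        pred, _, _ = predict(st, cfg)
        np.testing.assert_allclose(pred.Sig_lam, st.Sig_lam / 0.99)
        np.testing.assert_allclose(pred.Sig_beta, st.Sig_beta / 0.98)

    def test_inflation_is_psd_monotone(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(4, 4))
        Sig = A @ A.T
        cfg = FilterConfig(k3=0.95, k4=0.95)
        st = initialize(cfg, n=1, l=3)
        st.Sig_lam[0] = Sig
        pred, _, _ = predict(st, cfg)
        eig = np.linalg.eigvalsh(pred.Sig_lam[0] - Sig)
        assert eig.min() >= -1e-10

    def test_non_psd_prior_rejected(self):
        cfg = FilterConfig()
        st = initialize(cfg, n=2, l=1)
        st.Sig_lam[0] = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
        with pytest.raises(ValueError, match="PSD"):
            predict(st, cfg)


class TestEwmaUpdate:
    def _setup(self, k1=0.9, k2=0.9, n=1, l=1):
        cfg = FilterConfig(k1=k1, k2=k2, lags=1)
        st = initialize(cfg, n=n, l=l)
        return cfg, st

    def test_no_update_limit(self):
        cfg, st = self._setup(k1=1.0)
        V_hat, _, _, _ = ewma_update(st, np.array([5.0]), np.array([0.0, 0.0]), None, cfg)
        np.testing.assert_array_equal(V_hat, st.V)

    def test_pure_innovation_limit(self):
        cfg, st = self._setup(k1=1e-12)  # k1=0 limit (config requires > 0)
        V_hat, _, mu, _ = ewma_update(st, np.array([2.0]), np.array([0.0, 0.0]), None, cfg)
        assert mu[0] == 2.0
        assert V_hat[0] == pytest.approx(4.0, rel=1e-9)

    def test_geometric_decay_with_zero_residuals(self):
        """V_hat after 10 zero-residual steps with k1=0.9, V_0=1 is 0.9^10."""
        from tvpfavar.model import FilterState

        cfg, st = self._setup(k1=0.9)
        for _ in range(10):
            V_hat, _, mu, _ = ewma_update(st, np.array([0.0]), np.array([0.0, 0.0]), None, cfg)
            assert mu[0] == 0.0
            st = FilterState(st.lam, st.Sig_lam, st.beta, st.Sig_beta, V_hat, st.Q)
        assert st.V[0] == pytest.approx(0.9**10, rel=1e-12)

    def test_q_update_uses_var_residual(self):
        cfg, st = self._setup(k2=0.5, l=1)
        z = np.array([1.0, 2.0])
        w = np.array([1.0, 0.0, 0.0])  # beta = 0 so eps = z
        _, Q_hat, _, eps = ewma_update(st, np.array([0.0]), z, w, cfg)
        np.testing.assert_array_equal(eps, z)
        np.testing.assert_allclose(Q_hat, 0.5 * np.eye(2) + 0.5 * np.outer(z, z))


class TestKalmanUpdate:
    def test_zero_prediction_error_keeps_mean(self):
        cfg = FilterConfig(lags=1)
        st = initialize(cfg, n=2, l=1)
        z = np.array([1.0, -1.0])
        x = st.lam @ z  # exactly predicted
        w = np.array([1.0, 0.0, 0.0])
        V_hat, Q_hat, _, _ = ewma_update(st, x, z, w, cfg)
        out = kalman_update(st, x, z, w, V_hat, Q_hat)
        np.testing.assert_allclose(out.lam, st.lam, atol=1e-12)

    def test_covariance_trace_contracts(self):
        rng = np.random.default_rng(1)
        cfg = FilterConfig(lags=1)
        st = initialize(cfg, n=3, l=2)
        z = rng.normal(size=3)
        w = np.concatenate([[1.0], rng.normal(size=3)])
        x = rng.normal(size=3)
        V_hat, Q_hat, _, _ = ewma_update(st, x, z, w, cfg)
        out = kalman_update(st, x, z, w, V_hat, Q_hat)
        assert np.trace(out.Sig_lam.sum(axis=0)) <= np.trace(st.Sig_lam.sum(axis=0)) + 1e-12
        assert np.trace(out.Sig_beta) <= np.trace(st.Sig_beta) + 1e-12

    def test_filtered_beta_matches_conjugate_regression_oracle(self):
        """With forgetting 1 and constant known V, Q the filter is exact
        recursive Bayesian regression: terminal filtered states must match
        the closed-form posterior to 1e-6."""
        rng = np.random.default_rng(7)
        T, n, l, p = 30, 2, 1, 1
        k = l + 1
        Z = rng.normal(size=(T, k))
        X = rng.normal(size=(T, n))
        model = tf.TVPFAVAR(lags=p, k1=1.0, k2=1.0, k3=1.0, k4=1.0,
                            init_state_variance=4.0).fit(X, Z[:, 0], Z=Z)
        # lambda equations: scalar-observation regression on Z
        for i in range(n):
            post = rls_posterior(list(Z), list(X[:, i]), np.array([[1.0]]), 4.0)
            np.testing.assert_allclose(model.lambda_filtered_[-1, i], post, atol=1e-6)
        # beta: stacked regression of z_t on (1, z_{t-1})
        H_list, y_list = [], []
        for t in range(p, T):
            w = np.concatenate([[1.0], Z[t - 1]])
            H_list.append(np.kron(np.eye(k), w))
            y_list.append(Z[t])
        post_b = rls_posterior(H_list, y_list, np.eye(k), 4.0)
        np.testing.assert_allclose(model.beta_filtered_[-1], post_b, atol=1e-6)


class TestSmoother:
    def test_terminal_smoothed_equals_filtered(self, small_dgp):
        panel, _ = small_dgp
        m = tf.TVPFAVAR(n_factors=2, lags=2).fit(panel.X, panel.Y)
        np.testing.assert_array_equal(m.lambda_smoothed_[-1], m.lambda_filtered_[-1])
        np.testing.assert_array_equal(m.beta_smoothed_[-1], m.beta_filtered_[-1])

    def test_single_step_path_unchanged(self):
        means = np.random.default_rng(0).normal(size=(1, 3))
        covs = np.broadcast_to(np.eye(3), (1, 3, 3)).copy()
        sm, sc = smooth_gaussian_paths(means, covs, kappa=0.99)
        np.testing.assert_array_equal(sm, means)
        np.testing.assert_array_equal(sc, covs)

    def test_matches_independent_rts_oracle(self):
        """n=2, l=1, T=10 instance with forgetting 1 and known constant V, Q:
        smoothed means must match a textbook RTS smoother to 1e-6."""
        rng = np.random.default_rng(42)
        T, n, l, p = 10, 2, 1, 1
        k = l + 1
        Z = rng.normal(size=(T, k))
        X = rng.normal(size=(T, n))
        model = tf.TVPFAVAR(lags=p, k1=1.0, k2=1.0, k3=1.0, k4=1.0,
                            init_state_variance=4.0).fit(X, Z[:, 0], Z=Z)
        for i in range(n):
            m_f, m_s = kalman_rts_oracle(list(Z), list(X[:, i]), np.array([[1.0]]), 4.0)
            np.testing.assert_allclose(model.lambda_filtered_[:, i], m_f, atol=1e-6)
            np.testing.assert_allclose(model.lambda_smoothed_[:, i], m_s, atol=1e-6)
        H_list = [np.kron(np.eye(k), np.concatenate([[1.0], Z[t - 1]])) for t in range(p, T)]
        y_list = [Z[t] for t in range(p, T)]
        m_f, m_s = kalman_rts_oracle(H_list, y_list, np.eye(k), 4.0)
        np.testing.assert_allclose(model.beta_filtered_[p:], m_f, atol=1e-6)
        np.testing.assert_allclose(model.beta_smoothed_[p:], m_s, atol=1e-6)


class TestFit:
    def test_deterministic(self, small_dgp):
        panel, _ = small_dgp
        m1 = tf.TVPFAVAR(n_factors=2, lags=2).fit(panel.X, panel.Y)
        m2 = tf.TVPFAVAR(n_factors=2, lags=2).fit(panel.X, panel.Y)
        np.testing.assert_array_equal(m1.beta_smoothed_, m2.beta_smoothed_)
        np.testing.assert_array_equal(m1.lambda_smoothed_, m2.lambda_smoothed_)

    def test_too_short_sample_rejected(self):
        X = np.zeros((3, 2))
        with pytest.raises(ValueError, match="T > lags"):
            tf.TVPFAVAR(n_factors=1, lags=2).fit(X, np.zeros(3))

    def test_all_covariances_psd(self, small_dgp):
        panel, _ = small_dgp
        m = tf.TVPFAVAR(n_factors=2, lags=2).fit(panel.X, panel.Y)
        m.validate_psd()

    def test_smoothed_beta_flatter_under_constant_dgp(self):
        """Time-variation of the smoothed coefficient path is smaller when
        the DGP has constant coefficients than under strong drift."""
        def time_sd(coef_sd, seed):
            cfg = tf.DgpConfig(n_obs_series=10, n_factors=2, lags=2, T=150,
                               coef_innovation_sd=coef_sd,
                               loading_innovation_sd=0.0, seed=seed)
            panel, truth = tf.simulate_tvp_favar(cfg)
            Z = np.hstack([panel.Y.to_numpy()[:, None], truth.factor_path])
            m = tf.TVPFAVAR(lags=2).fit(panel.X.to_numpy(), panel.Y.to_numpy(), Z=Z)
            return m.beta_smoothed_[2:].std(axis=0).mean()

        flat = [time_sd(0.0, s) for s in range(3)]
        drift = [time_sd(0.1, s) for s in range(3)]
        assert np.median(flat) < np.median(drift)

    def test_sklearn_param_interface(self):
        m = tf.TVPFAVAR(k3=0.97)
        assert m.get_params()["k3"] == 0.97
        m.set_params(lags=3)
        assert m.lags == 3

    def test_state_serialization_round_trip(self, small_dgp, tmp_path):
        panel, _ = small_dgp
        m = tf.TVPFAVAR(n_factors=2, lags=2).fit(panel.X, panel.Y)
        m.save(tmp_path / "state.npz")
        data = np.load(tmp_path / "state.npz")
        np.testing.assert_array_equal(data["beta_smoothed_"], m.beta_smoothed_)
        assert (tmp_path / "state.json").exists()
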