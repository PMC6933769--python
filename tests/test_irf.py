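import numpy as np
import pytest

import tvpfavar as tf
from tvpfavar.irf import companion, irf_states, structural_impact


def _beta_matrix(blocks, k, intercept=None):
    """Stack VAR blocks into the (m, k) coefficient-matrix layout."""
    p = len(blocks)
    m = 1 + k * p
    B = np.zeros((m, k))
    if intercept is not None:
        B[0] = intercept
    for j, blk in enumerate(blocks):
        B[1 + j * k : 1 + (j + 1) * k, :] = blk.T
    return B


def _random_stable_var(rng, k, p):
    blocks = [rng.normal(0.0, 0.3 / (j + 1), (k, k)) for j in range(p)]
    B = _beta_matrix(blocks, k)
    A = companion(B, p, k)
    rho = np.max(np.abs(np.linalg.eigvals(A)))
    if rho >= 0.95:
        blocks = [blk * (0.9 / rho) ** (j + 1) for j, blk in enumerate(blocks)]
        B = _beta_matrix(blocks, k)
    return B, blocks


def _brute_force_irf(blocks, impact, H):
    """Iterate the VAR difference equation directly with the shock as the
    only innovation (independent of the companion-power construction)."""
    k = len(impact)
    p = len(blocks)
    path = np.zeros((H + 1 + p, k))
    path[p] = impact
    for h in range(1, H + 1):
        acc = np.zeros(k)
        for j, blk in enumerate(blocks, start=1):
            acc += blk @ path[p + h - j]
        path[p + h] = acc
    return path[p:]


class TestCompanion:
    def test_var1_companion_is_coefficient_block(self):
        rng = np.random.default_rng(0)
        blk = rng.normal(size=(3, 3))
        B = _beta_matrix([blk], 3)
        np.testing.assert_array_equal(companion(B, 1, 3), blk)

    def test_var2_block_structure(self):
        rng = np.random.default_rng(1)
        blocks = [rng.normal(size=(2, 2)) for _ in range(2)]
        A = companion(_beta_matrix(blocks, 2), 2, 2)
        assert A.shape == (4, 4)
        np.testing.assert_array_equal(A[:2, :2], blocks[0])
        np.testing.assert_array_equal(A[:2, 2:], blocks[1])
        np.testing.assert_array_equal(A[2:, :2], np.eye(2))
        np.testing.assert_array_equal(A[2:, 2:], np.zeros((2, 2)))

    def test_scalar_ar2_eigenvalues_are_lag_polynomial_roots(self):
        """AR(2) with roots 0.5 and 0.2: y_t = 0.7 y_{t-1} - 0.1 y_{t-2}."""
        B = _beta_matrix([np.array([[0.7]]), np.array([[-0.1]])], 1)
        eig = np.sort(np.linalg.eigvals(companion(B, 2, 1)).real)
        np.testing.assert_allclose(eig, [0.2, 0.5], atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            companion(np.zeros((4, 2)), 2, 2)


class TestStructuralImpact:
    def test_identity_covariance_gives_unit_vector(self):
        impact = structural_impact(np.eye(3), shock_index=0)
        np.testing.assert_allclose(impact, [1.0, 0.0, 0.0], atol=1e-12)

    def test_diagonal_covariance_scales_by_sd(self):
        Q = np.diag([4.0, 1.0, 1.0])
        impact = structural_impact(Q, shock_index=0)
        assert impact[0] == pytest.approx(2.0)

    def test_growth_first_ordering_matches_cholesky_column(self):
        Q = np.array([[1.0, 0.5], [0.5, 1.0]])
        impact = structural_impact(Q, shock_index=0, ordering=np.array([0, 1]))
        np.testing.assert_allclose(impact, np.linalg.cholesky(Q)[:, 0], atol=1e-12)

    def test_non_psd_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            structural_impact(np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestIrfStates:
    def test_diagonal_var1_closed_form(self):
        k = 3
        B = _beta_matrix([0.5 * np.eye(k)], k)
        resp = irf_states(B, np.eye(k), horizon=6, shock_index=0)
        for h in range(7):
            expected = np.zeros(k)
            expected[0] = 0.5**h
            np.testing.assert_allclose(resp[h], expected, atol=1e-12)

    def test_horizon_zero_is_structural_impact(self):
        rng = np.random.default_rng(2)
        B, _ = _random_stable_var(rng, 3, 2)
        Q = np.eye(3) + 0.1 * np.ones((3, 3))
        resp = irf_states(B, Q, horizon=0)
        np.testing.assert_allclose(resp[0], structural_impact(Q), atol=1e-12)

    @pytest.mark.parametrize("p", [1, 2, 3])
    def test_matches_brute_force_simulation(self, p):
        """Companion-power IRF equals direct iteration of the VAR
        difference equation, to 1e-10, for random stable systems."""
        rng = np.random.default_rng(p)
        for _ in range(20):
            k = rng.integers(2, 4)
            B, blocks = _random_stable_var(rng, k, p)
            A = rng.normal(size=(k, k))
            Q = A @ A.T + 0.1 * np.eye(k)
            impact = structural_impact(Q)
            resp = irf_states(B, Q, horizon=20)
            brute = _brute_force_irf(blocks, impact, 20)
            np.testing.assert_allclose(resp, brute, atol=1e-10)

    def test_linearity_in_shock_scale(self):
        rng = np.random.default_rng(5)
        B, _ = _random_stable_var(rng, 2, 2)
        Q = np.array([[1.0, 0.3], [0.3, 1.0]])
        r1 = irf_states(B, Q, horizon=10)
        r4 = irf_states(B, 4.0 * Q, horizon=10)
        np.testing.assert_allclose(r4, 2.0 * r1, atol=1e-10)

    def test_unstable_system_flagged_but_returned(self):
        B = _beta_matrix([1.05 * np.eye(2)], 2)
        with pytest.warns(UserWarning, match="unstable"):
            resp = irf_states(B, np.eye(2), horizon=5)
        assert np.all(np.isfinite(resp))


@pytest.fixture(scope="module")
def fitted(small_dgp):
    panel, _ = small_dgp
    return tf.TVPFAVAR(n_factors=2, lags=2).fit(panel.X, panel.Y)


class TestObservableIrf:

    def test_zero_loadings_zero_response(self, fitted):
        t = 40
        lam_save = fitted.lambda_smoothed_[t].copy()
        fitted.lambda_smoothed_[t] = 0.0
        try:
            resp = fitted.irf(t, horizon=8)
            np.testing.assert_array_equal(resp, 0.0)
        finally:
            fitted.lambda_smoothed_[t] = lam_save

    def test_growth_selector_loading_reproduces_state_response(self, fitted):
        t = 40
        lam_save = fitted.lambda_smoothed_[t].copy()
        e_y = np.zeros(fitted.k_)
        e_y[0] = 1.0
        fitted.lambda_smoothed_[t] = np.tile(e_y, (fitted.n_features_in_, 1))
        try:
            resp = fitted.irf(t, horizon=8)
            state = irf_states(fitted.beta_matrix(t), fitted.Q_smoothed_[t],
                               horizon=8, p=fitted.lags)
            for i in range(fitted.n_features_in_):
                np.testing.assert_allclose(resp[:, i], state[:, 0], atol=1e-12)
        finally:
            fitted.lambda_smoothed_[t] = lam_save

    def test_unknown_target_rejected(self, fitted):
        with pytest.raises(KeyError, match="unknown"):
            fitted.irf(10, targets=["nope"])


class TestIrfSurface:
    def test_surface_shape(self, small_dgp):
        panel, _ = small_dgp
        m = tf.TVPFAVAR(n_factors=2, lags=2).fit(panel.X, panel.Y)
        surf = m.irf_surface(horizon=8, targets=["x00", "x03"])
        assert surf.values.shape == (80, 9, 2)
        frame = surf.to_frame()
        assert len(frame) == 80 * 9 * 2

    def test_stable_system_decays_geometrically(self):
        """For a well-inside-the-unit-circle system the response at h=40 is
        below 1e-3 of its impact magnitude."""
        rng = np.random.default_rng(9)
        B, _ = _random_stable_var(rng, 3, 2)
        A = companion(B, 2, 3)
        assert np.max(np.abs(np.linalg.eigvals(A))) < 0.9
        resp = irf_states(B, np.eye(3), horizon=40)
        assert np.max(np.abs(resp[40])) < 1e-3 * max(np.max(np.abs(resp[0])), 1e-12)

    def test_constant_dgp_surface_flatter_than_drifting(self):
        """Origin-time variation of the IRF surface is smaller under a
        constant-parameter DGP than under coefficient drift."""
        def surface_variation(coef_sd, lam_sd, seed):
            cfg = tf.DgpConfig(n_obs_series=10, n_factors=2, lags=2, T=150,
                               coef_innovation_sd=coef_sd,
                               loading_innovation_sd=lam_sd, seed=seed)
            panel, truth = tf.simulate_tvp_favar(cfg)
            Z = np.hstack([panel.Y.to_numpy()[:, None], truth.factor_path])
            m = tf.TVPFAVAR(lags=2).fit(panel.X.to_numpy(), panel.Y.to_numpy(), Z=Z)
            surf = tf.irf_surface(m, horizon=6)
            return surf.values[10:].std(axis=0).mean()

        flat = np.median([surface_variation(0.0, 0.0, s) for s in range(3)])
        drift = np.median([surface_variation(0.08, 0.05, s) for s in range(3)])
        assert flat < drift
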