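import warnings

import numpy as np
import pytest

import tvpfavar as tf


@pytest.fixture(scope="session")
def small_dgp():
    """Small TVP-FAVAR draw with mild parameter drift."""
    cfg = tf.DgpConfig(
        n_obs_series=10,
        n_factors=2,
        lags=2,
        T=80,
        loading_innovation_sd=0.01,
        coef_innovation_sd=0.01,
        seed=42,
    )
    return tf.simulate_tvp_favar(cfg)


@pytest.fixture(scope="session")
def raw_panel():
    return tf.simulate_raw_panel(seed=11)


@pytest.fixture(scope="session")
def std_panel(raw_panel):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return tf.build_panel(raw_panel)


def rls_posterior(H_list, y_list, noise_cov, prior_var):
    """Conjugate Bayesian linear-regression posterior mean (oracle).

    Observations y_t = H_t beta + e_t, e_t ~ N(0, noise_cov), prior
    beta ~ N(0, prior_var * I).  Computed by direct normal equations,
    independent of any Kalman recursion.
    """
    d = H_list[0].shape[-1]
    Qinv = np.linalg.inv(np.atleast_2d(noise_cov))
    P = np.eye(d) / prior_var
    b = np.zeros(d)
    for H, y in zip(H_list, y_list):
        H = np.atleast_2d(H)
        y = np.atleast_1d(y)
        P += H.T @ Qinv @ H
        b += H.T @ Qinv @ y
    return np.linalg.solve(P, b)


def kalman_rts_oracle(H_list, y_list, noise_cov, prior_var):
    """Textbook Kalman filter + fixed-interval (RTS) smoother for a
    constant state observed through time-varying design matrices (oracle,
    coded directly from the standard equations)."""
    d = H_list[0].shape[-1]
    Qinv_dim = np.atleast_2d(noise_cov).shape[0]
    m = np.zeros(d)
    P = prior_var * np.eye(d)
    T = len(H_list)
    m_f = np.empty((T, d))
    P_f = np.empty((T, d, d))
    for t in range(T):
        H = np.atleast_2d(H_list[t])
        y = np.atleast_1d(y_list[t])
        S = np.atleast_2d(noise_cov) + H @ P @ H.T
        K = P @ H.T @ np.linalg.inv(S)
        m = m + K @ (y - H @ m)
        P = P - K @ H @ P
        m_f[t], P_f[t] = m, P
    # random walk with zero innovation: prediction is identity
    m_s = m_f.copy()
    P_s = P_f.copy()
    for t in range(T - 2, -1, -1):
        C = P_f[t] @ np.linalg.inv(P_f[t])  # = I; kept in oracle form
        m_s[t] = m_f[t] + C @ (m_s[t + 1] - m_f[t])
        P_s[t] = P_f[t] + C @ (P_s[t + 1] - P_f[t]) @ C.T
    return m_f, m_s
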