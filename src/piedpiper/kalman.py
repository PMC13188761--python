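"""Missing-aware Kalman recursions for independent local-level chains.

Each chain follows a scalar random walk with a known additive drift u_t
(covariate effects), process variance q and observation variance r:

    x_t = x_{t-1} + u_t + w_t,   w_t ~ N(0, q)
    y_t = x_t + v_t,             v_t ~ N(0, r)

Chains are stacked into (n_chains, T) arrays; NaN in ``y`` marks a missing
observation (prediction-only step). The log-likelihood kernel is the hot path
of maximum-likelihood fitting; a numba-compiled twin is used when numba is
importable and the pure-numpy implementation is the always-available
reference (the two are cross-checked in the test suite).
"""

from __future__ import annotations

import numpy as np

__all__ = ["loglik", "filter_pass", "smooth", "HAVE_NUMBA"]

_LOG_2PI = float(np.log(2.0 * np.pi))


def _loglik_numpy(y, u, q, r, m0, v0):
    nc, T = y.shape
    m = m0.copy()
    V = np.full(nc, v0)
    ll = 0.0
    for t in range(T):
        m = m + u[:, t]
        V = V + q
        yt = y[:, t]
        obs = np.isfinite(yt)
        if obs.any():
            S = V[obs] + r
            innov = yt[obs] - m[obs]
            ll += -0.5 * float(np.sum(np.log(S) + innov * innov / S))
            ll += -0.5 * _LOG_2PI * int(obs.sum())
            gain = V[obs] / S
            m[obs] = m[obs] + gain * innov
            V[obs] = V[obs] * (1.0 - gain)
    return ll


try:  # optional accelerator; numerics must match _loglik_numpy
    from numba import njit

    @njit(cache=True, error_model="numpy")
    def _loglik_numba(y, u, q, r, m0, v0):  # pragma: no cover - jit body
        nc, T = y.shape
        ll = 0.0
        for i in range(nc):
            m = m0[i]
            V = v0
            for t in range(T):
                m += u[i, t]
                V += q[i]
                yt = y[i, t]
                if yt == yt:  # observed (not NaN)
                    S = V + r
                    e = yt - m
                    ll += -0.5 * (np.log(S) + e * e / S + _LOG_2PI)
                    gain = V / S
                    m += gain * e
                    V *= 1.0 - gain
        return ll

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _loglik_numba = None
    HAVE_NUMBA = False


def loglik(y, u, q, r, m0, v0, engine: str = "auto") -> float:
    """Exact Gaussian marginal log-likelihood summed over independent chains.

    Parameters
    ----------
    y : (n_chains, T) observations, NaN = missing
    u : (n_chains, T) known drift (covariate effects) per step
    q : (n_chains,) process variance per chain
    r : scalar observation variance
    m0 : (n_chains,) prior mean of the pre-sample state x_0
    v0 : scalar prior variance of x_0 (diffuse)

    A degenerate parameter point (for example q = r = 0 against non-degenerate
    data) yields ``-inf`` rather than an exception, so optimizers can recover.
    """
    y = np.ascontiguousarray(y, dtype=float)
    u = np.ascontiguousarray(u, dtype=float)
    q = np.ascontiguousarray(q, dtype=float)
    m0 = np.ascontiguousarray(m0, dtype=float)
    if np.any(q < 0) or r < 0 or v0 < 0:
        return -np.inf
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        if engine == "numpy" or (engine == "auto" and not HAVE_NUMBA):
            out = _loglik_numpy(y, u, q, float(r), m0, float(v0))
        else:
            out = _loglik_numba(y, u, q, float(r), m0, float(v0))
    return float(out) if np.isfinite(out) else -np.inf


def filter_pass(y, u, q, r, m0, v0):
    """Full forward pass keeping the per-step quantities diagnostics need.

    Returns a dict of (n_chains, T) arrays: predicted and filtered state means
    and variances, innovations and their variances (NaN at missing steps).
    """
    y = np.asarray(y, dtype=float)
    u = np.asarray(u, dtype=float)
    q = np.asarray(q, dtype=float)
    nc, T = y.shape
    m_pred = np.empty((nc, T))
    v_pred = np.empty((nc, T))
    m_filt = np.empty((nc, T))
    v_filt = np.empty((nc, T))
    innov = np.full((nc, T), np.nan)
    s_innov = np.full((nc, T), np.nan)
    m = np.asarray(m0, dtype=float).copy()
    V = np.full(nc, float(v0))
    for t in range(T):
        m = m + u[:, t]
        V = V + q
        m_pred[:, t] = m
        v_pred[:, t] = V
        yt = y[:, t]
        obs = np.isfinite(yt)
        if obs.any():
            S = V[obs] + r
            e = yt[obs] - m[obs]
            innov[obs, t] = e
            s_innov[obs, t] = S
            gain = V[obs] / S
            m = m.copy()
            V = V.copy()
            m[obs] = m[obs] + gain * e
            V[obs] = V[obs] * (1.0 - gain)
        m_filt[:, t] = m
        v_filt[:, t] = V
    return {
        "m_pred": m_pred,
        "v_pred": v_pred,
        "m_filt": m_filt,
        "v_filt": v_filt,
        "innov": innov,
        "s_innov": s_innov,
    }


def smooth(y, u, q, r, m0, v0):
    """Fixed-interval (RTS) smoother: state means and variances given all data."""
    fp = filter_pass(y, u, q, r, m0, v0)
    m_filt, v_filt = fp["m_filt"], fp["v_filt"]
    m_pred, v_pred = fp["m_pred"], fp["v_pred"]
    nc, T = m_filt.shape
    m_smooth = m_filt.copy()
    v_smooth = v_filt.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        for t in range(T - 2, -1, -1):
            gain = np.where(v_pred[:, t + 1] > 0, v_filt[:, t] / v_pred[:, t + 1], 0.0)
            m_smooth[:, t] = m_filt[:, t] + gain * (m_smooth[:, t + 1] - m_pred[:, t + 1])
            v_smooth[:, t] = v_filt[:, t] + gain**2 * (
                v_smooth[:, t + 1] - v_pred[:, t + 1]
            )
    return m_smooth, v_smooth, fp
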