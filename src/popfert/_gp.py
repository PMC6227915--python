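"""Small Gaussian-process-over-time helpers (Matern-5/2 kernel).

Used by the fertility and sex-ratio-at-birth smoothers.  Kept explicit
(rather than delegating to a GP library) so the ST-GPR conventions —
fixed amplitude from residual spread, heteroscedastic data noise, a
non-zero prior mean curve — stay visible.
"""

from __future__ import annotations

import numpy as np

_SQRT5 = np.sqrt(5.0)


def matern52(t1, t2, length: float) -> np.ndarray:
    """Matern-5/2 correlation matrix between two sets of time points."""
    d = np.abs(np.subtract.outer(np.asarray(t1, float),
                                 np.asarray(t2, float))) / length
    return (1.0 + _SQRT5 * d + 5.0 * d * d / 3.0) * np.exp(-_SQRT5 * d)


def gp_posterior(t_obs, y_obs, noise_var, t_pred, length, amplitude,
                 mean_obs=None, mean_pred=None, jitter=1e-12):
    """Posterior mean and covariance of a GP with fixed hyperparameters.

    ``y_obs`` are observations at ``t_obs`` with per-point noise variance
    ``noise_var``; the prior mean curve is given at both observation and
    prediction points (zero when omitted).  Returns (mean, cov) at
    ``t_pred``.
    """
    t_pred = np.asarray(t_pred, float)
    a2 = amplitude ** 2
    K_pp = a2 * matern52(t_pred, t_pred, length)
    if t_obs is None or len(t_obs) == 0:
        mp = np.zeros(t_pred.size) if mean_pred is None else np.asarray(mean_pred)
        return mp.copy(), K_pp
    t_obs = np.asarray(t_obs, float)
    y = np.asarray(y_obs, float).copy()
    if mean_obs is not None:
        y = y - np.asarray(mean_obs, float)
    nv = np.broadcast_to(np.asarray(noise_var, float), t_obs.shape)
    K_oo = a2 * matern52(t_obs, t_obs, length) + np.diag(nv + jitter)
    K_po = a2 * matern52(t_pred, t_obs, length)
    sol = np.linalg.solve(K_oo, y)
    mean = K_po @ sol
    if mean_pred is not None:
        mean = mean + np.asarray(mean_pred, float)
    cov = K_pp - K_po @ np.linalg.solve(K_oo, K_po.T)
    return mean, cov


def gp_draws(mean, cov, n, rng, jitter=1e-10):
    """Draws from N(mean, cov) via a jittered Cholesky factor."""
    cov = np.asarray(cov, float)
    m = np.asarray(mean, float)
    k = m.size
    try:
        L = np.linalg.cholesky(cov + jitter * np.eye(k))
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(cov)
        L = V @ np.diag(np.sqrt(np.maximum(w, 0.0)))
    z = rng.standard_normal((n, k))
    return m[None, :] + z @ L.T


def tricube_smooth(t_obs, y_obs, t_pred, bandwidth, weights=None):
    """Tricube-kernel weighted moving average over time."""
    t_obs = np.asarray(t_obs, float)
    y_obs = np.asarray(y_obs, float)
    t_pred = np.asarray(t_pred, float)
    base = np.ones_like(y_obs) if weights is None else np.asarray(weights)
    out = np.zeros(t_pred.size)
    for i, t in enumerate(t_pred):
        u = np.abs(t_obs - t) / bandwidth
        w = np.where(u < 1, (1 - u ** 3) ** 3, 0.0) * base
        s = w.sum()
        out[i] = (w @ y_obs) / s if s > 0 else 0.0
    return out
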