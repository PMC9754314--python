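"""Linear-Gaussian state-space primitives.

Two flavours are provided: a fast scalar local-level filter (latent random
walk observed with noise) and a small general filter with time-varying
observation vectors used by the time-varying-coefficient regression. Both
expose the marginal log-likelihood via the prediction-error decomposition,
Rauch-Tung-Striebel smoothing, and forward-filtering backward-sampling.
"""
from __future__ import annotations

import math
from typing import Optional, Tuple

import numpy as np

_LOG2PI = math.log(2.0 * math.pi)
_JITTER = 1e-12


def local_level_loglik(
    y: np.ndarray, sigma_obs: float, sigma_mu: float, a1: float, p1_sd: float
) -> float:
    """Marginal log-likelihood of a local-level model.

    ``y[t] = mu[t] + N(0, sigma_obs)``, ``mu[t] = mu[t-1] + N(0, sigma_mu)``,
    ``mu[1] ~ N(a1, p1_sd)``. Pure-Python scalar loop (fast for short series
    and called inside MCMC).
    """
    H = sigma_obs * sigma_obs
    Q = sigma_mu * sigma_mu
    a = float(a1)
    p = p1_sd * p1_sd
    ll = 0.0
    for yt in y:
        f = p + H
        if f < _JITTER:
            f = _JITTER
        v = yt - a
        ll += -0.5 * (_LOG2PI + math.log(f) + v * v / f)
        k = p / f
        a += k * v
        p = p * (1.0 - k) + Q
    return ll


def local_level_filter(
    y: np.ndarray, sigma_obs: float, sigma_mu: float, a1: float, p1_sd: float
) -> Tuple[float, np.ndarray, np.ndarray]:
    """As :func:`local_level_loglik` but also returns the filtered means and
    variances (posterior of mu[t] given y[1..t])."""
    n = len(y)
    H = sigma_obs * sigma_obs
    Q = sigma_mu * sigma_mu
    att = np.empty(n)
    ptt = np.empty(n)
    a = float(a1)
    p = p1_sd * p1_sd
    ll = 0.0
    for t in range(n):
        f = max(p + H, _JITTER)
        v = y[t] - a
        ll += -0.5 * (_LOG2PI + math.log(f) + v * v / f)
        k = p / f
        a += k * v
        p_upd = p * (1.0 - k)
        att[t] = a
        ptt[t] = p_upd
        p = p_upd + Q
    return ll, att, ptt


def local_level_ffbs(
    y: np.ndarray,
    sigma_obs: float,
    sigma_mu: float,
    a1: float,
    p1_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one latent path from p(mu[1..T] | y, parameters)."""
    _, att, ptt = local_level_filter(y, sigma_obs, sigma_mu, a1, p1_sd)
    n = len(y)
    Q = sigma_mu * sigma_mu
    path = np.empty(n)
    path[-1] = rng.normal(att[-1], math.sqrt(max(ptt[-1], 0.0)))
    for t in range(n - 2, -1, -1):
        denom = ptt[t] + Q
        if denom < _JITTER:
            path[t] = att[t]
            continue
        g = ptt[t] / denom
        mean = att[t] + g * (path[t + 1] - att[t])
        var = ptt[t] * (1.0 - g)
        path[t] = rng.normal(mean, math.sqrt(max(var, 0.0)))
    return path


def local_level_smoother(
    y: np.ndarray, sigma_obs: float, sigma_mu: float, a1: float, p1_sd: float
) -> np.ndarray:
    """RTS-smoothed means of the latent level."""
    _, att, ptt = local_level_filter(y, sigma_obs, sigma_mu, a1, p1_sd)
    n = len(y)
    Q = sigma_mu * sigma_mu
    sm = np.empty(n)
    sm[-1] = att[-1]
    for t in range(n - 2, -1, -1):
        denom = ptt[t] + Q
        g = ptt[t] / denom if denom > _JITTER else 0.0
        sm[t] = att[t] + g * (sm[t + 1] - att[t])
    return sm


class TimeVaryingSSM:
    """State-space model with scalar observations and time-varying design.

    ``y[t] = Z[t] @ x[t] + N(0, sqrt(H))``,
    ``x[t+1] = T @ x[t] + N(0, Q)``, ``x[1] ~ N(a1, diag(P1))``.
    """

    def __init__(
        self,
        Z: np.ndarray,  # (n, m)
        T: np.ndarray,  # (m, m)
        a1: np.ndarray,  # (m,)
        P1_diag: np.ndarray,  # (m,)
    ):
        self.Z = np.asarray(Z, dtype=float)
        self.T = np.asarray(T, dtype=float)
        self.a1 = np.asarray(a1, dtype=float)
        self.P1 = np.diag(np.asarray(P1_diag, dtype=float))
        self.n, self.m = self.Z.shape

    def filter(
        self, y: np.ndarray, Q_diag: np.ndarray, H: float
    ) -> Tuple[float, np.ndarray, np.ndarray, np.ndarray]:
        """Kalman filter; returns (loglik, pointwise one-step log-densities,
        filtered means att (n,m), filtered covariances Ptt (n,m,m))."""
        Q = np.diag(np.asarray(Q_diag, dtype=float))
        a = self.a1.copy()
        P = self.P1.copy()
        n, m = self.n, self.m
        att = np.empty((n, m))
        ptt = np.empty((n, m, m))
        pointwise = np.empty(n)
        ll = 0.0
        for t in range(n):
            z = self.Z[t]
            pz = P @ z
            f = float(z @ pz) + H
            if f < _JITTER:
                f = _JITTER
            v = float(y[t] - z @ a)
            lpt = -0.5 * (_LOG2PI + math.log(f) + v * v / f)
            pointwise[t] = lpt
            ll += lpt
            k = pz / f
            a = a + k * v
            P = P - np.outer(k, pz)
            att[t] = a
            ptt[t] = P
            a = self.T @ a
            P = self.T @ P @ self.T.T + Q
        return ll, pointwise, att, ptt

    def loglik(self, y: np.ndarray, Q_diag: np.ndarray, H: float) -> float:
        return self.filter(y, Q_diag, H)[0]

    def smoother(
        self, y: np.ndarray, Q_diag: np.ndarray, H: float
    ) -> np.ndarray:
        """RTS-smoothed state means, shape (n, m)."""
        _, _, att, ptt = self.filter(y, Q_diag, H)
        Q = np.diag(np.asarray(Q_diag, dtype=float))
        n, m = self.n, self.m
        sm = np.empty((n, m))
        sm[-1] = att[-1]
        eye = np.eye(m) * _JITTER
        for t in range(n - 2, -1, -1):
            p_pred = self.T @ ptt[t] @ self.T.T + Q + eye
            G = ptt[t] @ self.T.T @ np.linalg.inv(p_pred)
            sm[t] = att[t] + G @ (sm[t + 1] - self.T @ att[t])
        return sm

    def ffbs(
        self,
        y: np.ndarray,
        Q_diag: np.ndarray,
        H: float,
        rng: np.random.Generator,
    ) -> np.ndarray:
        """One joint draw of the state path, shape (n, m)."""
        _, _, att, ptt = self.filter(y, Q_diag, H)
        Q = np.diag(np.asarray(Q_diag, dtype=float))
        n, m = self.n, self.m
        path = np.empty((n, m))
        eye = np.eye(m) * _JITTER
        path[-1] = _mvn_draw(att[-1], ptt[-1] + eye, rng)
        for t in range(n - 2, -1, -1):
            p_pred = self.T @ ptt[t] @ self.T.T + Q + eye
            G = ptt[t] @ self.T.T @ np.linalg.inv(p_pred)
            mean = att[t] + G @ (path[t + 1] - self.T @ att[t])
            cov = ptt[t] - G @ p_pred @ G.T
            path[t] = _mvn_draw(mean, cov + eye, rng)
        return path


def _mvn_draw(
    mean: np.ndarray, cov: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    cov = (cov + cov.T) / 2.0
    # eigen-clip: FFBS covariances can be numerically indefinite
    vals, vecs = np.linalg.eigh(cov)
    vals = np.clip(vals, 0.0, None)
    z = rng.standard_normal(len(mean))
    return mean + vecs @ (np.sqrt(vals) * z)
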