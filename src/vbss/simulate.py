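"""Seeded simulation of data from any model spec.

``simulate`` draws state noise before measurement noise at every sample from a
single seeded generator, so runs are bit-reproducible.
"""

from __future__ import annotations

from typing import Optional, Tuple, Union

import numpy as np

from .core import ModelSpec, TimeSeriesData, Trajectory

__all__ = ["simulate", "add_noise_snr"]


def _chol_psd(Q: np.ndarray) -> np.ndarray:
    # tolerate PSD (singular) structure matrices
    w, V = np.linalg.eigh((Q + Q.T) / 2)
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


def simulate(
    spec: ModelSpec,
    theta: np.ndarray,
    phi: np.ndarray,
    x0: np.ndarray,
    u: Optional[np.ndarray],
    T: Optional[int] = None,
    state_precision: float = np.inf,
    noise_precision: float = np.inf,
    seed: Union[int, np.random.Generator] = 0,
    cov_structure: Optional[np.ndarray] = None,
) -> Tuple[TimeSeriesData, Trajectory]:
    """Simulate ``(y, x)`` from the generative model.

    Gaussian state noise has covariance ``Q / state_precision`` (``Q`` the
    optional structure matrix, identity by default).  Continuous observations
    add Gaussian noise with variance ``1 / noise_precision``; binary
    observations are Bernoulli draws with success probability ``g``.  Infinite
    precisions give exact deterministic propagation.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    if u is None:
        if T is None:
            raise ValueError("provide u or T")
        u = np.zeros((0, T))
    u = np.atleast_2d(np.asarray(u, dtype=float))
    if T is None:
        T = u.shape[1]
    n = spec.n

    L = None
    if n and np.isfinite(state_precision):
        Q = np.eye(n) if cov_structure is None else np.asarray(cov_structure, float)
        L = _chol_psd(Q / state_precision)

    x = np.zeros((n, T))
    y = np.zeros((0, T))
    xc = x0
    if spec.g_takes_trajectory:
        for t in range(T):
            ut = u[:, t] if u.size else np.zeros(0)
            xc = np.atleast_1d(np.asarray(spec.f(xc, theta, ut, spec.extras), float))
            if L is not None:
                xc = xc + L @ rng.standard_normal(n)
            if not np.all(np.isfinite(xc)):
                raise FloatingPointError(f"non-finite state at t={t}")
            x[:, t] = xc
        y = np.atleast_2d(np.asarray(spec.g(x, phi, u, spec.extras), float))
        if spec.source == "binary":
            raise ValueError("trajectory observations must be continuous")
        if np.isfinite(noise_precision):
            y = y + rng.standard_normal(y.shape) / np.sqrt(noise_precision)
        data = TimeSeriesData(y=y, u=u, dt=spec.dt)
        return data, Trajectory(x=x, x0=x0)
    rows = []
    for t in range(T):
        ut = u[:, t] if u.size else np.zeros(0)
        if n:
            xc = np.atleast_1d(np.asarray(spec.f(xc, theta, ut, spec.extras), float))
            if L is not None:
                xc = xc + L @ rng.standard_normal(n)
            if not np.all(np.isfinite(xc)):
                raise FloatingPointError(f"non-finite state at t={t}")
            x[:, t] = xc
        gt = np.atleast_1d(np.asarray(spec.g(xc, phi, ut, spec.extras), float))
        if spec.source == "binary":
            if np.any(gt < 0) or np.any(gt > 1):
                raise ValueError("g outside [0, 1] for binary source")
            rows.append((rng.random(gt.size) < gt).astype(float))
        else:
            if np.isfinite(noise_precision):
                gt = gt + rng.standard_normal(gt.size) / np.sqrt(noise_precision)
            rows.append(gt)
    y = np.column_stack(rows) if rows else y
    data = TimeSeriesData(y=y, u=u, dt=spec.dt)
    return data, Trajectory(x=x, x0=x0)


def add_noise_snr(
    clean: np.ndarray, snr_db: float, seed: Union[int, np.random.Generator] = 0
) -> np.ndarray:
    """Add white Gaussian noise at a given signal-to-noise ratio (decibels).

    Noise variance is ``var(clean) / 10**(snr_db / 10)``, i.i.d. across
    channels and time.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    clean = np.asarray(clean, dtype=float)
    v = float(np.var(clean))
    if v <= 0:
        raise ValueError("add_noise_snr requires a non-constant signal")
    sd = np.sqrt(v / 10.0 ** (snr_db / 10.0))
    return clean + sd * rng.standard_normal(clean.shape)
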