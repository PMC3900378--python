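"""Posterior containers and shared numerics for the VB-Laplace engine."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy.special import digamma, gammaln

from ..core import GaussianPrior

__all__ = [
    "GammaStats",
    "StateStats",
    "Posterior",
    "InversionReport",
    "gaussian_kl",
    "gamma_kl",
    "free_indices",
    "sym",
    "safe_inv",
    "slogdet_psd",
]

_FIXED_TOL = 1e-12


@dataclass
class GammaStats:
    """Gamma sufficient statistics (shape, rate); optionally clamped to a point."""

    a: float
    b: float
    fixed_value: Optional[float] = None

    @property
    def mean(self) -> float:
        if self.fixed_value is not None:
            return self.fixed_value
        return self.a / self.b

    @property
    def e_log(self) -> float:
        if self.fixed_value is not None:
            return float(np.log(self.fixed_value))
        return float(digamma(self.a) - np.log(self.b))


@dataclass
class StateStats:
    """Per-time Gaussian statistics of the hidden states.

    ``cross[t]`` holds ``Cov(x_{t-1}, x_t)`` (with ``x_0`` the initial
    condition for ``t = 0``), as produced by the lagged forward pass.
    """

    means: np.ndarray            # (n, T)
    covs: np.ndarray             # (T, n, n)
    cross: np.ndarray            # (T, n, n)
    # joint statistics of (x_{t-1}, x_t) under a single conditioning set
    # (y_{1:t+k}); the free-energy transition and entropy terms need the
    # pair's mean/covariance to be mutually consistent
    pair_means: Optional[np.ndarray] = None   # (T, 2n)
    pair_covs: Optional[np.ndarray] = None    # (T, 2n, 2n)
    x0_smoothed: Optional[GaussianPrior] = None


@dataclass
class Posterior:
    theta: GaussianPrior
    phi: GaussianPrior
    x0: GaussianPrior
    states: Optional[StateStats] = None
    state_precision: GammaStats = field(default_factory=lambda: GammaStats(1.0, 1.0))
    noise_precision: GammaStats = field(default_factory=lambda: GammaStats(1.0, 1.0))
    # Post-hoc joint Laplace covariance over (theta, x0, phi), for
    # identifiability diagnostics; mean-field blocks alone carry no
    # between-block covariance.
    joint_param_cov: Optional[np.ndarray] = None

    def copy(self) -> "Posterior":
        import copy

        return copy.deepcopy(self)


@dataclass
class InversionReport:
    free_energy_trace: List[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    residuals: Optional[np.ndarray] = None
    predictions: Optional[np.ndarray] = None
    fit: dict = field(default_factory=dict)

    @property
    def free_energy(self) -> float:
        return self.free_energy_trace[-1] if self.free_energy_trace else np.nan


def free_indices(cov: np.ndarray) -> np.ndarray:
    """Indices of coordinates with non-zero prior variance.

    Zero-variance entries are legal and mean the coordinate is fixed to its
    prior mean throughout the inversion.
    """
    if cov.size == 0:
        return np.zeros(0, dtype=int)
    return np.flatnonzero(np.diag(cov) > _FIXED_TOL)


def sym(M: np.ndarray) -> np.ndarray:
    return (M + M.T) / 2.0


def safe_inv(M: np.ndarray, jitter: float = 1e-10) -> np.ndarray:
    M = sym(np.atleast_2d(M))
    if M.size == 0:
        return M
    d = M.shape[0]
    try:
        return np.linalg.inv(M + jitter * np.trace(M) / d * np.eye(d))
    except np.linalg.LinAlgError:
        return np.linalg.pinv(M)


def slogdet_psd(M: np.ndarray, floor: float = 1e-32) -> float:
    M = sym(np.atleast_2d(M))
    if M.size == 0:
        return 0.0
    w = np.linalg.eigvalsh(M)
    return float(np.sum(np.log(np.clip(w, floor, None))))


def gaussian_kl(q: GaussianPrior, p: GaussianPrior) -> float:
    """KL(q || p) over the coordinates with non-zero prior variance."""
    free = free_indices(p.covariance)
    if free.size == 0:
        return 0.0
    dm = (q.mean - p.mean)[free]
    Sq = q.covariance[np.ix_(free, free)]
    Sp = p.covariance[np.ix_(free, free)]
    Pp = safe_inv(Sp)
    d = free.size
    return float(
        0.5
        * (
            np.trace(Pp @ Sq)
            + dm @ Pp @ dm
            - d
            + slogdet_psd(Sp)
            - slogdet_psd(Sq)
        )
    )


def gamma_kl(q: GammaStats, a0: float, b0: float) -> float:
    """KL(Gamma(a, b) || Gamma(a0, b0)); zero when q is a clamped point mass."""
    if q.fixed_value is not None:
        return 0.0
    a, b = q.a, q.b
    return float(
        (a - a0) * digamma(a)
        - gammaln(a)
        + gammaln(a0)
        + a0 * (np.log(b) - np.log(b0))
        + a * (b0 - b) / b
    )
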