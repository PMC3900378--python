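"""Core model/data/prior types for nonlinear stochastic state-space models.

The canonical generative model is

    x_t = f(x_{t-1}, theta, u_t) + eta_t,      eta_t ~ N(0, Q / alpha)
    y_t = g(x_t,     phi,   u_t) + eps_t,      eps_t ~ N(0, I / sigma)

for continuous data, or y_t ~ Bernoulli(g(x_t, phi, u_t)) for binary data.
``alpha`` (state-noise precision) and ``sigma`` (measurement-noise precision)
carry Gamma priors; ``theta``, ``phi`` and the initial condition ``x0`` carry
Gaussian priors.  Time conventions: ``x_1 = f(x0, theta, u_1)`` and
``y_t = g(x_t, phi, u_t)``; input column ``t`` feeds both the transition into
``t`` and the observation at ``t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

__all__ = [
    "TimeSeriesData",
    "ModelSpec",
    "GaussianPrior",
    "GammaPrior",
    "PriorBundle",
    "InversionOptions",
    "Trajectory",
    "Problem",
    "validate",
    "numeric_jacobian",
]

Mapping = Callable[[np.ndarray, np.ndarray, np.ndarray, dict], np.ndarray]


@dataclass
class TimeSeriesData:
    """Observations ``y`` (p x T), inputs ``u`` (m x T) and an exclusion mask.

    ``exclusion_mask[i, t] = True`` removes sample ``(i, t)`` from the
    likelihood.  Missing cells read from CSV become excluded samples.
    """

    y: np.ndarray
    u: Optional[np.ndarray] = None
    exclusion_mask: Optional[np.ndarray] = None
    dt: Optional[float] = None

    def __post_init__(self) -> None:
        self.y = np.atleast_2d(np.asarray(self.y, dtype=float))
        T = self.y.shape[1]
        if self.u is None:
            self.u = np.zeros((0, T))
        self.u = np.atleast_2d(np.asarray(self.u, dtype=float))
        if self.exclusion_mask is None:
            self.exclusion_mask = ~np.isfinite(self.y)
        self.exclusion_mask = np.asarray(self.exclusion_mask, dtype=bool)
        if self.exclusion_mask.shape != self.y.shape:
            raise ValueError("exclusion_mask and y must share shape")
        if self.u.shape[1] != T and self.u.size:
            raise ValueError("u must have T columns")

    @property
    def p(self) -> int:
        return self.y.shape[0]

    @property
    def T(self) -> int:
        return self.y.shape[1]


@dataclass
class ModelSpec:
    """Evolution/observation mappings and dimensions.

    Mappings use the standardized form ``f(x, P, u, extras) -> ndarray``.
    Optional analytic derivatives may be attached (``df_dx``, ``df_dp``,
    ``dg_dx``, ``dg_dp`` with the same signature, returning Jacobians); when
    absent, numerical differentiation is used internally.
    """

    f: Optional[Mapping]
    g: Mapping
    n: int
    n_theta: int
    n_phi: int
    source: str = "continuous"  # 'continuous' | 'binary'
    n_micro: int = 1
    delay_matrix: Optional[np.ndarray] = None
    extras: dict = field(default_factory=dict)
    dt: float = 1.0
    f_takes_history: bool = False
    # g maps the whole state trajectory (n, T) -> (p, T); only supported by
    # deterministic inversions (convolution-style observations).
    g_takes_trajectory: bool = False
    df_dx: Optional[Mapping] = None
    df_dp: Optional[Mapping] = None
    dg_dx: Optional[Mapping] = None
    dg_dp: Optional[Mapping] = None

    def __post_init__(self) -> None:
        if self.source not in ("continuous", "binary"):
            raise ValueError("source must be 'continuous' or 'binary'")
        if self.n_micro < 1:
            raise ValueError("n_micro must be >= 1")
        if self.delay_matrix is not None:
            dm = np.asarray(self.delay_matrix, dtype=int)
            if np.any(dm < 0):
                raise ValueError("delays must be >= 0")
            self.delay_matrix = dm


@dataclass
class GaussianPrior:
    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.covariance = np.atleast_2d(np.asarray(self.covariance, dtype=float))
        if self.mean.size == 0:
            self.covariance = self.covariance.reshape(0, 0)
        if self.covariance.shape != (self.mean.size, self.mean.size):
            raise ValueError("covariance shape must match mean")
        if self.mean.size and not np.allclose(
            self.covariance, self.covariance.T, atol=1e-10
        ):
            raise ValueError("covariance must be symmetric within 1e-10")

    @property
    def dim(self) -> int:
        return self.mean.size

    @classmethod
    def standard(cls, dim: int, mean: float = 0.0, var: float = 1.0) -> "GaussianPrior":
        return cls(np.full(dim, float(mean)), np.eye(dim) * var)


@dataclass
class GammaPrior:
    """Gamma(shape a, rate b); mean a/b, variance a/b^2."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError("Gamma shape and rate must be positive")

    @property
    def mean(self) -> float:
        return self.a / self.b

    @property
    def variance(self) -> float:
        return self.a / self.b**2


@dataclass
class PriorBundle:
    theta: GaussianPrior
    phi: GaussianPrior
    x0: GaussianPrior
    state_precision: GammaPrior = field(default_factory=lambda: GammaPrior(1.0, 1.0))
    noise_precision: GammaPrior = field(default_factory=lambda: GammaPrior(1.0, 1.0))
    state_noise_cov_structure: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.state_noise_cov_structure is not None:
            Q = np.atleast_2d(np.asarray(self.state_noise_cov_structure, dtype=float))
            w = np.linalg.eigvalsh((Q + Q.T) / 2)
            if w.min() < -1e-10:
                raise ValueError("state_noise_cov_structure must be PSD")
            self.state_noise_cov_structure = Q

    @classmethod
    def default(cls, spec: ModelSpec) -> "PriorBundle":
        """Weakly informative defaults: N(0, I) blocks, Gamma(1, 1) precisions."""
        return cls(
            theta=GaussianPrior.standard(spec.n_theta),
            phi=GaussianPrior.standard(spec.n_phi),
            x0=GaussianPrior.standard(spec.n),
        )


@dataclass
class InversionOptions:
    lag_k: int = 0
    max_iter: int = 32
    tol_dF: float = 2e-2
    seed: int = 0
    deterministic_limit: bool = False
    verbose: bool = False
    # Fixing a precision turns its Gamma factor into a point mass (the
    # deterministic limit does this implicitly for the state precision).
    fixed_noise_precision: Optional[float] = None
    fixed_state_precision: Optional[float] = None
    gn_max_iter: int = 32
    jitter: float = 1e-8

    def __post_init__(self) -> None:
        if self.tol_dF <= 0:
            raise ValueError("tol_dF must be > 0")
        if self.lag_k < 0:
            raise ValueError("lag_k must be >= 0")


@dataclass
class Trajectory:
    x: np.ndarray
    x0: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        self.x0 = np.atleast_1d(np.asarray(self.x0, dtype=float))
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.x0))):
            raise ValueError("trajectory entries must be finite")


@dataclass
class Problem:
    """A validated (spec, data, priors) triple."""

    spec: ModelSpec
    data: TimeSeriesData
    priors: PriorBundle

    @property
    def Q(self) -> np.ndarray:
        if self.priors.state_noise_cov_structure is not None:
            return self.priors.state_noise_cov_structure
        return np.eye(self.spec.n)


def validate(spec: ModelSpec, data: TimeSeriesData, priors: PriorBundle) -> Problem:
    """Cross-check dimensions and evaluate the mappings once at prior means.

    Returns a pass-through :class:`Problem` record.  Raises ``ValueError`` on
    dimension mismatch, non-finite mapping output at the prior means, or
    binary data containing values outside {0, 1}.
    """
    if priors.theta.dim != spec.n_theta:
        raise ValueError("theta prior dimension mismatch")
    if priors.phi.dim != spec.n_phi:
        raise ValueError("phi prior dimension mismatch")
    if priors.x0.dim != spec.n:
        raise ValueError("x0 prior dimension mismatch")
    if priors.state_noise_cov_structure is not None and (
        priors.state_noise_cov_structure.shape != (spec.n, spec.n)
    ):
        raise ValueError("state_noise_cov_structure must be n x n")
    u1 = data.u[:, 0] if data.u.size else np.zeros(0)
    if spec.n > 0:
        if spec.f is None:
            raise ValueError("dynamic model (n > 0) requires an evolution mapping")
        fx = np.atleast_1d(
            np.asarray(spec.f(priors.x0.mean, priors.theta.mean, u1, spec.extras))
        )
        if fx.shape != (spec.n,):
            raise ValueError(
                f"f output dimension {fx.shape} does not match n={spec.n}"
            )
        if not np.all(np.isfinite(fx)):
            raise ValueError("non-finite evolution output at prior means")
        gx_in = fx
    else:
        gx_in = np.zeros(0)
    if spec.g_takes_trajectory:
        traj = np.tile(gx_in[:, None], (1, data.T))
        gy = np.atleast_2d(
            np.asarray(spec.g(traj, priors.phi.mean, data.u, spec.extras))
        )
        if gy.shape != (data.p, data.T):
            raise ValueError(
                f"g output shape {gy.shape} does not match (p, T)=({data.p}, {data.T})"
            )
        if not np.all(np.isfinite(gy)):
            raise ValueError("non-finite observation output at prior means")
    else:
        gx = np.atleast_1d(np.asarray(spec.g(gx_in, priors.phi.mean, u1, spec.extras)))
        if gx.shape != (data.p,):
            raise ValueError(f"g output dimension {gx.shape} does not match p={data.p}")
        if not np.all(np.isfinite(gx)):
            raise ValueError("non-finite observation output at prior means")
    if spec.source == "binary":
        kept = data.y[~data.exclusion_mask]
        if not np.all(np.isin(kept, (0.0, 1.0))):
            raise ValueError("binary data must contain only {0, 1}")
    return Problem(spec=spec, data=data, priors=priors)


def numeric_jacobian(
    mapping: Callable[[np.ndarray], np.ndarray],
    point: np.ndarray,
    rel_step: float = 1e-4,
) -> np.ndarray:
    """Central-difference Jacobian of ``mapping`` at ``point``.

    Step for coordinate ``j`` is ``rel_step * max(1, |point_j|)``.  Used
    internally whenever analytic gradients are not supplied.
    """
    point = np.atleast_1d(np.asarray(point, dtype=float))
    f0 = np.atleast_1d(np.asarray(mapping(point), dtype=float))
    J = np.zeros((f0.size, point.size))
    for j in range(point.size):
        h = rel_step * max(1.0, abs(point[j]))
        xp = point.copy()
        xm = point.copy()
        xp[j] += h
        xm[j] -= h
        fp = np.atleast_1d(np.asarray(mapping(xp), dtype=float))
        fm = np.atleast_1d(np.asarray(mapping(xm), dtype=float))
        if not (np.all(np.isfinite(fp)) and np.all(np.isfinite(fm))):
            raise ValueError("non-finite evaluation within the difference stencil")
        J[:, j] = (fp - fm) / (2 * h)
    return J


def spec_replace(spec: ModelSpec, **kw) -> ModelSpec:
    return replace(spec, **kw)
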