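"""Design-efficiency scoring for parameter estimation and model selection.

Parameter estimation uses A-optimality (trace of the expected posterior
parameter covariance).  Model selection uses the Laplace-Chernoff risk, an
analytic approximation to the Bayes selection error rate between the prior
(or current-posterior) predictive densities of the candidate models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    InversionOptions,
    ModelSpec,
    PriorBundle,
    TimeSeriesData,
    numeric_jacobian,
)
from .inversion.common import free_indices, safe_inv, sym
from .inversion.engine import (
    deterministic_trajectory,
    predict_observations,
)

__all__ = [
    "PredictiveDensity",
    "prior_predictive",
    "chernoff_risk",
    "a_optimality",
    "online_design_step",
    "block_design",
]


@dataclass
class PredictiveDensity:
    """First-order (delta-method) Gaussian density of the data prediction."""

    mean: np.ndarray
    covariance: np.ndarray
    model_id: str = ""

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.covariance = np.atleast_2d(np.asarray(self.covariance, dtype=float))


def _composed_prediction(spec: ModelSpec, priors: PriorBundle, u: np.ndarray):
    u = np.atleast_2d(np.asarray(u, dtype=float))
    T = u.shape[1]
    th_f = free_indices(priors.theta.covariance)
    x0_f = free_indices(priors.x0.covariance)
    ph_f = free_indices(priors.phi.covariance)
    mth, mx0, mph = priors.theta.mean, priors.x0.mean, priors.phi.mean

    def pred(v):
        th = mth.copy()
        x0v = mx0.copy()
        ph = mph.copy()
        th[th_f] = v[: th_f.size]
        x0v[x0_f] = v[th_f.size: th_f.size + x0_f.size]
        ph[ph_f] = v[th_f.size + x0_f.size:]
        if spec.n:
            xm = deterministic_trajectory(spec, th, x0v, u, T)
        else:
            xm = np.zeros((0, T))
        return predict_observations(spec, xm, ph, u, T).ravel()

    v0 = np.concatenate([mth[th_f], mx0[x0_f], mph[ph_f]])
    Sprior = np.zeros((v0.size, v0.size))
    off = 0
    for cov, fidx in (
        (priors.theta.covariance, th_f),
        (priors.x0.covariance, x0_f),
        (priors.phi.covariance, ph_f),
    ):
        if fidx.size:
            Sprior[off: off + fidx.size, off: off + fidx.size] = cov[
                np.ix_(fidx, fidx)
            ]
        off += fidx.size
    return pred, v0, Sprior


def prior_predictive(
    spec: ModelSpec, priors: PriorBundle, u: np.ndarray, model_id: str = ""
) -> PredictiveDensity:
    """Delta-method predictive density of the data under a (deterministic)
    model: mean = prediction at the prior means; covariance = J Sigma J' plus
    the expected measurement noise (prior-mean precision's inverse, b/a)."""
    pred, v0, Sprior = _composed_prediction(spec, priors, u)
    mean = pred(v0)
    if not np.all(np.isfinite(mean)):
        raise FloatingPointError("non-finite prediction at prior means")
    if v0.size:
        J = numeric_jacobian(pred, v0)
        cov = J @ Sprior @ J.T
    else:
        cov = np.zeros((mean.size, mean.size))
    if spec.source == "binary":
        g = np.clip(mean, 1e-6, 1 - 1e-6)
        cov = cov + np.diag(g * (1 - g))
    else:
        noise_var = priors.noise_precision.b / priors.noise_precision.a
        cov = cov + noise_var * np.eye(mean.size)
    return PredictiveDensity(mean, sym(cov), model_id)


def chernoff_risk(pred1: PredictiveDensity, pred2: PredictiveDensity) -> float:
    """Laplace-Chernoff approximation to the model-selection error rate.

    For two a-priori equiprobable models with similar predictive variances,
    ``risk = 1/2 exp(-(1/8) dg' Sigma^-1 dg)`` with ``dg`` the difference in
    the first-order moments of the data predictions and ``Sigma`` the average
    predictive covariance.  Lies in [0, 1/2]; maximal when the predictions
    coincide; symmetric in its arguments.
    """
    if pred1.mean.size != pred2.mean.size:
        raise ValueError("predictive densities must share dimension")
    dg = pred1.mean - pred2.mean
    Sbar = 0.5 * (pred1.covariance + pred2.covariance)
    q = float(dg @ safe_inv(Sbar) @ dg)
    return float(0.5 * np.exp(-q / 8.0))


def a_optimality(spec: ModelSpec, priors: PriorBundle, u: np.ndarray) -> float:
    """Trace of the expected posterior parameter covariance (lower is better):
    ``trace((Sigma0^-1 + J' J / noise_var)^-1)`` under the delta method."""
    pred, v0, Sprior = _composed_prediction(spec, priors, u)
    if v0.size == 0:
        return 0.0
    J = numeric_jacobian(pred, v0)
    P0 = safe_inv(Sprior)
    if spec.source == "binary":
        g = np.clip(pred(v0), 1e-6, 1 - 1e-6)
        w = g * (1 - g)
        H = J.T @ ((1.0 / w)[:, None] * J) + P0
    else:
        noise_var = priors.noise_precision.b / priors.noise_precision.a
        H = (J.T @ J) / noise_var + P0
    return float(np.trace(safe_inv(H)))


@dataclass
class DesignChoice:
    index: int
    risks: np.ndarray
    efficiency: float


def online_design_step(
    candidates: Sequence[np.ndarray],
    models: Sequence[Tuple[ModelSpec, PriorBundle]],
    history_u: Optional[np.ndarray] = None,
) -> DesignChoice:
    """Score each candidate input block by the Laplace-Chernoff risk of the
    model comparison (current posteriors standing as priors) and return the
    argmin; ties break in candidate order.

    When ``history_u`` is given, predictions are computed over the full
    concatenated design and the risk is evaluated on the candidate block's
    samples, so carried-over dynamics (e.g. convolution tails) are honoured.
    """
    if len(candidates) == 0:
        raise ValueError("empty candidate list")
    if len(models) != 2:
        raise ValueError("online design step compares exactly two models")
    risks = np.zeros(len(candidates))
    for c, cand in enumerate(candidates):
        cand = np.atleast_2d(np.asarray(cand, dtype=float))
        if history_u is not None and history_u.size:
            u_full = np.concatenate([history_u, cand], axis=1)
        else:
            u_full = cand
        preds = []
        for spec, priors in models:
            pd = prior_predictive(spec, priors, u_full)
            p = pd.mean.size // u_full.shape[1]
            nb = cand.shape[1] * p
            sl = slice(pd.mean.size - nb, pd.mean.size)
            preds.append(
                PredictiveDensity(pd.mean[sl], pd.covariance[sl, sl])
            )
        risks[c] = chernoff_risk(preds[0], preds[1])
    best = int(np.argmin(risks))
    return DesignChoice(index=best, risks=risks, efficiency=float(-risks[best]))


def block_design(
    n_blocks: int,
    attention_blocks: Sequence[int],
    block_on: int = 16,
    block_off: int = 16,
) -> np.ndarray:
    """Boxcar two-regressor design: photic stimulation on during every
    stimulation period, attention gating the chosen blocks' stimulation
    periods.  Returns u (2 x n_blocks*(block_on+block_off)): row 0 photic,
    row 1 attention."""
    L = block_on + block_off
    u = np.zeros((2, n_blocks * L))
    att = set(attention_blocks)
    for b in range(n_blocks):
        sl = slice(b * L, b * L + block_on)
        u[0, sl] = 1.0
        if b in att:
            u[1, sl] = 1.0
    return u
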