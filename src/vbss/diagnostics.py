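"""Post-inversion diagnostics.

Residual autocorrelation against white-noise bands, fit summaries, posterior
parameter correlation (identifiability), and first-order Volterra
decomposition of any series onto lagged inputs (the hidden states' impulse
response to experimentally controlled inputs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .inversion.common import Posterior

__all__ = [
    "residual_acf",
    "one_step_innovations",
    "fit_summary",
    "posterior_correlation",
    "volterra_kernels",
    "VolterraResult",
]


def one_step_innovations(problem, posterior) -> np.ndarray:
    """One-step-ahead prediction errors ``y_t - g(f(x_{t-1|t-1}))`` from a
    filtering pass at the converged posterior.

    Under a correctly specified state-space model these innovations are
    (approximately) white; serial correlation flags unmodelled state-noise
    structure, which smoothed residuals can mask.
    """
    from .core import InversionOptions
    from .inversion.engine import update_states_lagged, _ut

    spec, data = problem.spec, problem.data
    p0 = update_states_lagged(problem, posterior, InversionOptions(lag_k=0))
    m = p0.states.means
    T = data.T
    e = np.zeros((data.p, T))
    prev = posterior.x0.mean
    for t in range(T):
        ut = _ut(data.u, t)
        fx = np.atleast_1d(np.asarray(
            spec.f(prev, posterior.theta.mean, ut, spec.extras), float))
        gx = np.atleast_1d(np.asarray(
            spec.g(fx, posterior.phi.mean, ut, spec.extras), float))
        e[:, t] = data.y[:, t] - gx
        prev = m[:, t]
    return e


def residual_acf(residuals: np.ndarray, max_lag: int = 40) -> Tuple[np.ndarray, float]:
    """Per-channel normalized sample autocorrelation up to ``max_lag``.

    Returns (acf, band): acf has shape (p, max_lag+1) with lag 0 equal to 1;
    band is the +-1.96/sqrt(T) 95% white-noise band.  NaN entries (excluded
    samples) are ignored channel-wise.
    """
    r = np.atleast_2d(np.asarray(residuals, dtype=float))
    p, T = r.shape
    if T <= max_lag:
        raise ValueError("need T > max_lag")
    out = np.zeros((p, max_lag + 1))
    for i in range(p):
        x = r[i][np.isfinite(r[i])]
        x = x - x.mean()
        v = float(x @ x)
        if v <= 0:
            raise ValueError("constant residuals have no autocorrelation")
        for lag in range(max_lag + 1):
            out[i, lag] = float(x[lag:] @ x[: x.size - lag]) / v
    band = 1.96 / np.sqrt(T)
    return out, band


def fit_summary(data, posterior: Posterior, spec, predictions: np.ndarray) -> dict:
    """Variance explained (continuous) or balanced accuracy (binary), plus the
    log-likelihood at the posterior means."""
    keep = ~data.exclusion_mask
    y = data.y[keep]
    pred = predictions[keep]
    out = {}
    if spec.source == "binary":
        gc = np.clip(pred, 1e-8, 1 - 1e-8)
        out["log_likelihood"] = float(
            np.sum(y * np.log(gc) + (1 - y) * np.log1p(-gc))
        )
        yhat = (pred >= 0.5).astype(float)
        acc = [
            float(np.mean(yhat[y == c] == c)) for c in (0.0, 1.0) if np.any(y == c)
        ]
        out["balanced_accuracy"] = float(np.mean(acc)) if acc else np.nan
    else:
        tss = float(np.sum((y - y.mean()) ** 2))
        if tss <= 0:
            raise ValueError("zero total sum of squares")
        rss = float(np.sum((y - pred) ** 2))
        out["variance_explained"] = 100.0 * (1.0 - rss / tss)
        sig = posterior.noise_precision.mean
        out["log_likelihood"] = float(
            -0.5 * y.size * np.log(2 * np.pi / sig) - 0.5 * sig * rss
        )
    return out


def posterior_correlation(posterior: Posterior) -> np.ndarray:
    """Correlation matrix over (theta, phi) from the joint Laplace covariance.

    Requires ``posterior.joint_param_cov`` (computed by the deterministic
    inversion); zero-variance (fixed) parameters get zero correlation rows.
    Near-unity off-diagonal magnitudes diagnose poor identifiability.
    """
    if posterior.joint_param_cov is None:
        raise ValueError("posterior carries no joint parameter covariance")
    C = posterior.joint_param_cov
    nth = posterior.theta.dim
    nx0 = posterior.x0.dim
    idx = np.concatenate(
        [np.arange(nth), nth + nx0 + np.arange(posterior.phi.dim)]
    ).astype(int)
    S = C[np.ix_(idx, idx)]
    sd = np.sqrt(np.clip(np.diag(S), 0, None))
    R = np.zeros_like(S)
    ok = sd > 0
    R[np.ix_(ok, ok)] = S[np.ix_(ok, ok)] / np.outer(sd[ok], sd[ok])
    np.fill_diagonal(R, np.where(ok, 1.0, 0.0))
    return R


@dataclass
class VolterraResult:
    kernels: np.ndarray        # (n_series, n_inputs, depth)
    standard_errors: np.ndarray
    intercepts: np.ndarray
    r_squared: np.ndarray

    def significant(self, z: float = 2.0) -> np.ndarray:
        return np.abs(self.kernels) > z * self.standard_errors


def volterra_kernels(
    series: np.ndarray, inputs: np.ndarray, depth: int = 16
) -> VolterraResult:
    """First-order Volterra kernels of each series onto lagged inputs.

    Ordinary least squares of ``series[i, t]`` onto ``inputs[j, t - lag]``
    for lags 0..depth-1 (intercept included); standard errors assume
    homoscedastic residuals.  Identifies the impulse response of, e.g.,
    estimated hidden states to controlled inputs.
    """
    X = np.atleast_2d(np.asarray(series, dtype=float))
    U = np.atleast_2d(np.asarray(inputs, dtype=float))
    ns, T = X.shape
    m = U.shape[0]
    if T <= depth * m:
        raise ValueError("series too short for requested depth")
    cols = [np.ones(T - depth + 1)]
    for j in range(m):
        for lag in range(depth):
            cols.append(U[j, depth - 1 - lag: T - lag])
    D = np.column_stack(cols)  # (T-depth+1, 1 + m*depth)
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        raise ValueError("rank-deficient lagged design")
    DtD_inv = np.linalg.inv(D.T @ D)
    kernels = np.zeros((ns, m, depth))
    ses = np.zeros((ns, m, depth))
    intercepts = np.zeros(ns)
    r2 = np.zeros(ns)
    for i in range(ns):
        yv = X[i, depth - 1:]
        beta = DtD_inv @ (D.T @ yv)
        resid = yv - D @ beta
        dof = max(yv.size - D.shape[1], 1)
        s2 = float(resid @ resid) / dof
        se = np.sqrt(s2 * np.diag(DtD_inv))
        intercepts[i] = beta[0]
        kernels[i] = beta[1:].reshape(m, depth)
        ses[i] = se[1:].reshape(m, depth)
        tss = float(np.sum((yv - yv.mean()) ** 2))
        r2[i] = 1.0 - float(resid @ resid) / tss if tss > 0 else np.nan
    return VolterraResult(kernels, ses, intercepts, r2)
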