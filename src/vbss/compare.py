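"""Subject-level and group-level Bayesian model selection.

Free energies stand in for log model evidences throughout.  Group-level
selection treats the model identity as a random effect with a Dirichlet
population distribution (variational updates between per-subject attributions
and Dirichlet counts), and summarizes it with expected model frequencies and
exceedance probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import betainc, digamma, logsumexp

from .core import GaussianPrior
from .inversion.common import free_indices, safe_inv, slogdet_psd

__all__ = [
    "posterior_model_probs",
    "family_posterior",
    "savage_dickey",
    "group_bms",
    "GroupBMSResult",
]


def posterior_model_probs(
    free_energies: np.ndarray, prior: Optional[np.ndarray] = None
) -> np.ndarray:
    """Softmax of (F + log prior): posterior model probabilities."""
    F = np.asarray(free_energies, dtype=float)
    if not np.any(np.isfinite(F)):
        raise ValueError("all free energies are -inf")
    if prior is None:
        prior = np.full(F.size, 1.0 / F.size)
    logp = F + np.log(np.asarray(prior, dtype=float))
    return np.exp(logp - logsumexp(logp))


def family_posterior(
    model_probs: np.ndarray, partition: Sequence[int]
) -> np.ndarray:
    """Family posterior probabilities under a disjoint partition of models.

    ``partition[i]`` is the family label of model ``i``; each family's
    probability is the sum of its members'.  The model prior is assumed
    uniform within and across families (rebalance the model prior upstream if
    families have unequal sizes and a flat family prior is wanted).
    """
    probs = np.asarray(model_probs, dtype=float)
    labels = np.asarray(partition)
    if labels.size != probs.size:
        raise ValueError("partition must cover all models exactly once")
    fams = np.unique(labels)
    return np.array([probs[labels == f].sum() for f in fams])


def savage_dickey(
    posterior: GaussianPrior,
    full_prior: GaussianPrior,
    reduced_prior: GaussianPrior,
) -> float:
    """Log Bayes factor (reduced vs full) by Gaussian model reduction.

    The reduced model must be nested in the full one: its prior differs only
    by shrunk/shifted moments (zero variance = fixing coordinates).  Exact
    for linear-Gaussian models.  Point reductions use the Savage-Dickey
    density ratio of posterior to prior marginals at the reduction point.
    """
    d = full_prior.dim
    if not (posterior.dim == d == reduced_prior.dim):
        raise ValueError("dimension mismatch")
    free_full = set(free_indices(full_prior.covariance).tolist())
    free_red = set(free_indices(reduced_prior.covariance).tolist())
    if not free_red.issubset(free_full):
        raise ValueError("reduced prior is not nested in the full prior")
    fixed = sorted(free_full - free_red)
    kept = sorted(free_red)

    lbf = 0.0
    if fixed:
        idx = np.array(fixed, int)
        v = reduced_prior.mean[idx]
        for dist in (posterior, full_prior):
            mu = dist.mean[idx]
            S = dist.covariance[np.ix_(idx, idx)]
            Si = safe_inv(S)
            ld = slogdet_psd(S)
            val = -0.5 * (
                idx.size * np.log(2 * np.pi) + ld + (v - mu) @ Si @ (v - mu)
            )
            lbf += val if dist is posterior else -val
    if kept:
        idx = np.array(kept, int)
        Sf = full_prior.covariance[np.ix_(idx, idx)]
        Sr = reduced_prior.covariance[np.ix_(idx, idx)]
        if not (
            np.allclose(Sf, Sr)
            and np.allclose(full_prior.mean[idx], reduced_prior.mean[idx])
        ):
            # general Gaussian reduction on the kept coordinates
            P = safe_inv(posterior.covariance[np.ix_(idx, idx)])
            P0 = safe_inv(Sf)
            Q0 = safe_inv(Sr)
            mu = posterior.mean[idx]
            mu0 = full_prior.mean[idx]
            nu0 = reduced_prior.mean[idx]
            Pt = P + Q0 - P0
            ht = P @ mu + Q0 @ nu0 - P0 @ mu0
            c = mu @ P @ mu + nu0 @ Q0 @ nu0 - mu0 @ P0 @ mu0
            lbf += 0.5 * (
                slogdet_psd(P)
                + slogdet_psd(Q0)
                - slogdet_psd(P0)
                - slogdet_psd(Pt)
                + ht @ safe_inv(Pt) @ ht
                - c
            )
    return float(lbf)


@dataclass
class GroupBMSResult:
    dirichlet_counts: np.ndarray
    expected_frequencies: np.ndarray
    exceedance: np.ndarray
    attributions: np.ndarray
    fixed_effects_log_evidence: np.ndarray

    @property
    def best_model(self) -> int:
        return int(np.argmax(self.exceedance))


def _exceedance(counts: np.ndarray, n_draws: int, seed: int) -> np.ndarray:
    K = counts.size
    if K == 2:
        # P(r1 > r2) = P(r1 > 1/2) under Beta(a1, a2)
        p1 = 1.0 - betainc(counts[0], counts[1], 0.5)
        return np.array([p1, 1.0 - p1])
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(counts, size=n_draws)
    win = np.argmax(draws, axis=1)
    return np.bincount(win, minlength=K) / n_draws


def group_bms(
    log_evidence: np.ndarray,
    prior_counts: Optional[np.ndarray] = None,
    n_draws: int = 2**16,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 512,
) -> GroupBMSResult:
    """Random-effects Bayesian model selection over S subjects x K models.

    Iterates between per-subject model attributions and Dirichlet counts
    until the counts change by less than ``tol``.  Exceedance probabilities
    (the chance a model is more frequent than all rivals) use the exact Beta
    integral for K = 2 and seeded Dirichlet Monte-Carlo otherwise.  The
    fixed-effects log group Bayes factor (column sums of log evidence) is
    reported alongside.
    """
    L = np.atleast_2d(np.asarray(log_evidence, dtype=float))
    S, K = L.shape
    if K < 2:
        raise ValueError("need at least two models")
    if not np.all(np.isfinite(L)):
        raise ValueError("log evidences must be finite")
    alpha0 = (
        np.ones(K) if prior_counts is None else np.asarray(prior_counts, dtype=float)
    )
    alpha = alpha0 + S / K
    for _ in range(max_iter):
        logu = L + (digamma(alpha) - digamma(alpha.sum()))
        logu -= logsumexp(logu, axis=1, keepdims=True)
        u = np.exp(logu)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    logu = L + (digamma(alpha) - digamma(alpha.sum()))
    logu -= logsumexp(logu, axis=1, keepdims=True)
    u = np.exp(logu)
    return GroupBMSResult(
        dirichlet_counts=alpha,
        expected_frequencies=alpha / alpha.sum(),
        exceedance=_exceedance(alpha, n_draws, seed),
        attributions=u,
        fixed_effects_log_evidence=L.sum(axis=0),
    )
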