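"""Structural transforms mapping special cases into the canonical state-space form.

Delay embedding, AR(1) state-noise augmentation and microtime refinement all
return a new :class:`~vbss.core.ModelSpec` on a (possibly augmented) state
space, so that the one inversion engine handles every special case.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Tuple

import numpy as np

from .core import ModelSpec

__all__ = ["embed_delays", "augment_ar1", "with_microtime"]


def _max_delay(spec: ModelSpec) -> int:
    if spec.delay_matrix is None:
        raise ValueError("embed_delays requires a delay_matrix")
    return int(np.max(spec.delay_matrix))


def embed_delays(spec: ModelSpec) -> ModelSpec:
    """Embed a delayed (non-Markovian) evolution into an augmented Markov state.

    The augmented state stacks the history newest-first,
    ``X_t = (x_t, x_{t-1}, ..., x_{t-D})`` with ``D`` the maximum delay, so the
    new dimension is ``n * (D + 1)``.  The top block applies ``f`` reading
    delayed coordinates (or the whole history when ``spec.f_takes_history``);
    lower blocks shift the history; the observation reads the current block.
    """
    D = _max_delay(spec)
    if D == 0 and not spec.f_takes_history:
        return spec
    n = spec.n
    nX = n * (D + 1)
    f0, g0 = spec.f, spec.g
    dm = spec.delay_matrix

    if spec.f_takes_history:
        def top(X, p, u, ex):
            return np.atleast_1d(np.asarray(f0(X, p, u, ex), dtype=float))
    elif dm.ndim == 1:
        idx = np.asarray([dm[j] * n + j for j in range(n)])

        def top(X, p, u, ex):
            return np.atleast_1d(np.asarray(f0(X[idx], p, u, ex), dtype=float))
    else:
        rows = [np.asarray([dm[i, j] * n + j for j in range(n)]) for i in range(n)]

        def top(X, p, u, ex):
            out = np.empty(n)
            for i in range(n):
                fi = np.atleast_1d(np.asarray(f0(X[rows[i]], p, u, ex), dtype=float))
                out[i] = fi[i]
            return out

    def f_emb(X, p, u, ex):
        Xn = np.empty(nX)
        Xn[:n] = top(X, p, u, ex)
        Xn[n:] = X[: nX - n]
        return Xn

    def g_emb(X, p, u, ex):
        return g0(X[:n], p, u, ex)

    return replace(
        spec,
        f=f_emb,
        g=g_emb,
        n=nX,
        delay_matrix=None,
        f_takes_history=False,
        df_dx=None,
        df_dp=None,
        dg_dx=None,
        dg_dp=None,
    )


def augment_ar1(spec: ModelSpec, decay: float) -> Tuple[ModelSpec, np.ndarray]:
    """Augment the state with an AR(1) noise carrier ``z``.

    Evolution on the augmented state ``(x, z)`` is
    ``x' = f(x) + z`` and ``z' = decay * z``, with ``z`` receiving fresh state
    noise each step.  Returns the augmented spec together with a state-noise
    covariance structure whose ``x`` block is down-weighted (factor 1e-4) so
    that ``z`` carries the stochastic drive.  ``decay = 0`` degenerates to
    white (one-step-delayed) noise on ``x``.
    """
    if not (0.0 <= decay < 1.0):
        raise ValueError("decay must lie in [0, 1)")
    n = spec.n
    f0, g0 = spec.f, spec.g

    def f_aug(X, p, u, ex):
        x, z = X[:n], X[n:]
        out = np.empty(2 * n)
        out[:n] = np.atleast_1d(np.asarray(f0(x, p, u, ex), dtype=float)) + z
        out[n:] = decay * z
        return out

    def g_aug(X, p, u, ex):
        return g0(X[:n], p, u, ex)

    Q = np.diag(np.concatenate([np.full(n, 1e-4), np.ones(n)]))
    new = replace(
        spec,
        f=f_aug,
        g=g_aug,
        n=2 * n,
        df_dx=None,
        df_dp=None,
        dg_dx=None,
        dg_dp=None,
    )
    return new, Q


def with_microtime(spec: ModelSpec, n_micro: int) -> ModelSpec:
    """Refine the evolution on a microtime grid of ``n_micro`` Euler sub-steps.

    The single-step map is applied ``n_micro`` times per sample with step
    ``delta = dt / n_micro`` (mappings read the step from ``extras['step']``).
    State noise still enters only at the times where data are sampled, so
    stochastic effects between samples are not modelled.
    """
    if n_micro < 1:
        raise ValueError("n_micro must be >= 1")
    if n_micro == 1:
        return spec
    f0 = spec.f
    base_step = spec.extras.get("step", spec.dt)
    sub = base_step / n_micro

    def f_micro(x, p, u, ex):
        ex2 = dict(ex)
        ex2["step"] = sub
        for _ in range(n_micro):
            x = np.atleast_1d(np.asarray(f0(x, p, u, ex2), dtype=float))
        return x

    return replace(spec, f=f_micro, n_micro=n_micro, df_dx=None, df_dp=None)
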