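"""Registered evolution/observation mappings.

All mappings are pure functions with the standardized signature
``fn(x, P, u, extras) -> ndarray`` and are looked up by name in
:data:`REGISTRY`, so JSON model files can reference them.

Contents: Rescorla-Wagner value learning with optional utility/learning-rate
asymmetry and a go/no-go softmax readout; a bilinear neural evolution with a
double-gamma hemodynamic convolution readout for fMRI network models;
Q-learning with a dynamic (input-driven) learning rate; classic benchmark
vector fields (Lorenz, Van der Pol, double well, linear feedback); a sigmoid
classifier; and a two-level random-effects GLM builder.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.special import expit as sigmoid

from .core import GaussianPrior, ModelSpec, PriorBundle

__all__ = [
    "REGISTRY",
    "sigmoid",
    "rw_evolution",
    "go_nogo_softmax",
    "dcm_evolution",
    "hrf_kernel",
    "hrf_observation",
    "qlearn_dynamic_rate_evolution",
    "lorenz_evolution",
    "vanderpol_evolution",
    "double_well_evolution",
    "linear_feedback_evolution",
    "sigmoid_classifier_observation",
    "rfx_glm_spec",
    "make_spec",
]


# ---------------------------------------------------------------------------
# reinforcement learning

def rw_evolution(x, p, u, extras):
    """Rescorla-Wagner value update ``x + alpha * (utility(u) - x)``.

    ``u = (feedback,)`` with feedback in {-1, 0, +1}; neutral feedback (0)
    carries zero utility.  ``extras['variant']`` selects the asymmetry:

    - ``'utility'``:  p = (alpha_raw, b_plus, b_minus); utility = b+ * u for
      gains, b- * u for losses.
    - ``'learning'``: p = (alpha_plus_raw, alpha_minus_raw, b); the learning
      rate depends on the feedback sign.
    - ``'both'``:     p = (a+_raw, a-_raw, b+, b-).
    - ``'none'``:     p = (alpha_raw, b).

    Learning rates pass through a sigmoid so they stay in (0, 1).  When
    ``extras['gated']`` is true, no-go trials (``u[1] == 0``) freeze learning.
    """
    variant = extras.get("variant", "none")
    fb = float(u[0]) if len(u) else 0.0
    if extras.get("gated", False) and len(u) > 1 and u[1] == 0:
        return np.atleast_1d(x).astype(float)
    x = float(np.atleast_1d(x)[0])
    if variant == "utility":
        a = sigmoid(p[0])
        util = p[1] * fb if fb > 0 else (p[2] * fb if fb < 0 else 0.0)
    elif variant == "learning":
        a = sigmoid(p[0]) if fb > 0 else (sigmoid(p[1]) if fb < 0 else sigmoid(p[0]))
        util = p[2] * fb
    elif variant == "both":
        a = sigmoid(p[0]) if fb >= 0 else sigmoid(p[1])
        util = p[2] * fb if fb > 0 else (p[3] * fb if fb < 0 else 0.0)
    else:
        a = sigmoid(p[0])
        util = p[1] * fb
    return np.atleast_1d(x + a * (util - x))


def go_nogo_softmax(x, p, u, extras):
    """P(go) = sigmoid(x - bias); P(no-go) is its complement."""
    bias = p[0] if len(np.atleast_1d(p)) else 0.0
    return np.atleast_1d(sigmoid(float(np.atleast_1d(x)[0]) - bias))


# ---------------------------------------------------------------------------
# bilinear (DCM-style) network dynamics + hemodynamic convolution readout

def dcm_evolution(x, p, u, extras):
    """Euler step of the bilinear neural field
    ``x + dt (A x + sum_j u_j B_j x + C u + sum_j x_j D_j x)``.

    Matrices are carried in ``extras``: 'A' (n x n), 'B' (m x n x n),
    'C' (n x m), 'D' (n x n x n, optional).  Entries of ``p`` overwrite the
    positions listed in ``extras['theta_map']`` (matrix name, index tuple), so
    any subset of couplings can be free parameters.
    """
    n = x.size
    A = np.array(extras.get("A", np.zeros((n, n))), dtype=float)
    m = u.size
    B = np.array(extras.get("B", np.zeros((m, n, n))), dtype=float)
    C = np.array(extras.get("C", np.zeros((n, m))), dtype=float)
    D = extras.get("D")
    tmap = extras.get("theta_map", [])
    mats = {"A": A, "B": B, "C": C}
    if D is not None:
        D = np.array(D, dtype=float)
        mats["D"] = D
    for pj, (name, idx) in zip(np.atleast_1d(p), tmap):
        mats[name][tuple(idx)] = pj
    dt = extras.get("step", extras.get("dt", 1.0))
    dx = mats["A"] @ x
    for j in range(m):
        dx = dx + u[j] * (mats["B"][j] @ x)
    if m:
        dx = dx + mats["C"] @ u
    if "D" in mats:
        for j in range(n):
            dx = dx + x[j] * (mats["D"][j] @ x)
    return x + dt * dx


def hrf_kernel(length: int = 16, dt: float = 1.0, p1: float = 6.0, p2: float = 16.0,
               ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic impulse response, unit peak."""
    from scipy.stats import gamma as gamma_dist

    tt = np.arange(length) * dt
    k = gamma_dist.pdf(tt, p1) - ratio * gamma_dist.pdf(tt, p2)
    return k / np.max(np.abs(k)) if np.max(np.abs(k)) > 0 else k


def hrf_observation(neural: np.ndarray, gains: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Linear convolution of each region's neural trajectory with the
    hemodynamic kernel, scaled by a per-region gain."""
    neural = np.atleast_2d(neural)
    T = neural.shape[1]
    if kernel.size > T:
        raise ValueError("kernel longer than series")
    out = np.zeros_like(neural, dtype=float)
    for i in range(neural.shape[0]):
        out[i] = gains[i] * np.convolve(neural[i], kernel)[:T]
    return out


# ---------------------------------------------------------------------------
# dynamic learning rate Q-learning

def qlearn_fixed_rate_evolution(x, p, u, extras):
    """Standard two-armed Q-learning: state (q1, q2), p = (alpha_raw,),
    u = (choice in {0,1}, feedback)."""
    q1, q2 = x
    choice, fb = float(u[0]), float(u[1])
    a = sigmoid(p[0])
    if choice >= 0.5:
        q2 = q2 + a * (fb - q2)
    else:
        q1 = q1 + a * (fb - q1)
    return np.array([q1, q2])


def qlearn_random_walk_rate_evolution(x, p, u, extras):
    """Q-learning whose (inverse-sigmoid) learning rate is a random-walk
    hidden state: state (q1, q2, r), u = (choice, feedback, ...); the rate
    state r carries no deterministic dynamics (state noise drives it)."""
    q1, q2, r = x
    choice, fb = float(u[0]), float(u[1])
    rate = sigmoid(r)
    if choice >= 0.5:
        q2 = q2 + rate * (fb - q2)
    else:
        q1 = q1 + rate * (fb - q1)
    return np.array([q1, q2, r])


def q_diff_softmax(x, phi, u, extras):
    """P(choose action 2) = sigmoid(beta * (q2 - q1)); beta in extras."""
    beta = extras.get("beta", 1.0)
    return np.atleast_1d(sigmoid(beta * (x[1] - x[0])))


def qlearn_dynamic_rate_evolution(x, p, u, extras):
    """Q-learning with an input-driven learning rate.

    State ``x = (q1, q2, r, dr)``: two action values, the inverse-sigmoid
    transformed learning rate ``r`` and its discrete derivative ``dr``.
    Input ``u = (choice in {0,1}, feedback, instability in {0,1})``.
    Parameters ``p = (omega_raw, decay_raw)``: ``omega = omega_raw`` weighs
    the impact of winning-action instability on the learning rate and
    ``decay = sigmoid(decay_raw)`` in (0, 1) sets the impulse-response decay.
    Only the chosen action's value is updated, with rate ``sigmoid(r)``.
    """
    q1, q2, r, dr = x
    choice, fb, inst = (float(u[0]), float(u[1]), float(u[2]))
    omega = p[0]
    decay = sigmoid(p[1])
    rate = sigmoid(r)
    if choice >= 0.5:
        q2 = q2 + rate * (fb - q2)
    else:
        q1 = q1 + rate * (fb - q1)
    dr_new = decay * dr + omega * inst
    r_new = r + dr_new
    return np.array([q1, q2, r_new, dr_new])


# ---------------------------------------------------------------------------
# benchmark vector fields (Euler steps; use with_microtime for refinement)

def lorenz_evolution(x, p, u, extras):
    """Euler step of the Lorenz system; p = (sigma, rho, beta)."""
    s, r, b = (p[0], p[1], p[2]) if len(np.atleast_1d(p)) >= 3 else (10.0, 28.0, 8 / 3)
    dt = extras.get("step", extras.get("dt", 0.01))
    dx = np.array(
        [s * (x[1] - x[0]), x[0] * (r - x[2]) - x[1], x[0] * x[1] - b * x[2]]
    )
    return x + dt * dx


def vanderpol_evolution(x, p, u, extras):
    """Euler step of the Van der Pol oscillator; p = (mu,)."""
    mu = p[0] if len(np.atleast_1d(p)) else 1.0
    dt = extras.get("step", extras.get("dt", 0.01))
    return x + dt * np.array([x[1], mu * (1 - x[0] ** 2) * x[1] - x[0]])


def double_well_evolution(x, p, u, extras):
    """Euler step of an overdamped double-well particle; p = (depth,)."""
    a = p[0] if len(np.atleast_1d(p)) else 1.0
    dt = extras.get("step", extras.get("dt", 0.01))
    return x + dt * np.atleast_1d(-4 * a * x * (x**2 - 1))


def linear_feedback_evolution(x, p, u, extras):
    """Linear map ``M x + c u`` with M in extras (optionally overwritten by p)."""
    M = np.array(extras["M"], dtype=float)
    tmap = extras.get("theta_map", [])
    for pj, idx in zip(np.atleast_1d(p), tmap):
        M[tuple(idx)] = pj
    out = M @ x
    Cg = extras.get("C")
    if Cg is not None and u.size:
        out = out + np.asarray(Cg, float) @ u
    return out


# ---------------------------------------------------------------------------
# static observation mappings

def hrf_conv_observation(x_traj, phi, u, extras):
    """Trajectory-level observation: per-region HRF convolution of the neural
    states.  Kernel built from extras ('kernel_length', 'kernel_dt'); gains
    are phi when present, else extras['gains']."""
    x_traj = np.atleast_2d(x_traj)
    kern = hrf_kernel(
        int(extras.get("kernel_length", 16)), float(extras.get("kernel_dt", 1.0))
    )
    phi = np.atleast_1d(phi)
    gains = phi if phi.size else np.asarray(
        extras.get("gains", np.ones(x_traj.shape[0])), dtype=float
    )
    return hrf_observation(x_traj, gains, kern)


def sigmoid_classifier_observation(x, phi, u, extras):
    """P(y=1) = sigmoid(A . u + b); a static (n = 0) binary model."""
    phi = np.atleast_1d(phi)
    return np.atleast_1d(sigmoid(float(phi[:-1] @ u + phi[-1])))


def identity_observation(x, phi, u, extras):
    return np.atleast_1d(x).astype(float)


def linear_observation(x, phi, u, extras):
    """y = X phi with the design row carried in u."""
    return np.atleast_1d(u @ phi)


# ---------------------------------------------------------------------------
# random-effects GLM (two-level static hierarchy)

def rfx_glm_evolution(x, th, u, ex):
    """Broadcast the group mean into every subject's effect state."""
    return np.full(x.size, float(th[0]))


def rfx_glm_observation(x, ph, u, ex):
    """Each subject's observations load on their own effect (identity,
    repeated ex['reps'] times)."""
    return np.repeat(x, ex.get("reps", 1))


def rfx_glm_spec(S: int, group_mean_prior: Optional[GaussianPrior] = None,
                 h0: bool = False):
    """Two-level random-effects model for S subjects' scalar effects.

    The group mean is an evolution parameter broadcast into the S subject
    states in one step (``x_1 = mean * 1 + eta``); the state-noise precision
    is the between-subject precision.  Each subject's observations load on
    their own state (identity loading).  ``h0 = True`` pins the group mean at
    zero.  Returns (spec, priors); observations are (S*reps) x 1.
    """
    if S < 2:
        raise ValueError("need S >= 2 subjects")
    spec = ModelSpec(
        f=rfx_glm_evolution, g=rfx_glm_observation, n=S, n_theta=1, n_phi=0,
        source="continuous", extras={"reps": 1},
        df_dx=lambda x, th, u, ex: np.zeros((x.size, x.size)),
        df_dp=lambda x, th, u, ex: np.ones((x.size, 1)),
    )
    gm = group_mean_prior or GaussianPrior(np.zeros(1), np.eye(1) * 4.0)
    if h0:
        gm = GaussianPrior(np.zeros(1), np.zeros((1, 1)))
    priors = PriorBundle(
        theta=gm,
        phi=GaussianPrior(np.zeros(0), np.zeros((0, 0))),
        x0=GaussianPrior(np.zeros(S), np.zeros((S, S))),
    )
    return spec, priors


# ---------------------------------------------------------------------------

def make_spec(name: str, **kw) -> ModelSpec:
    """Build a ModelSpec for a registered observation/evolution pairing."""
    if name == "sigmoid_classifier":
        n_features = kw.get("n_features", 2)
        return ModelSpec(
            f=None, g=sigmoid_classifier_observation, n=0, n_theta=0,
            n_phi=n_features + 1, source="binary",
        )
    raise KeyError(name)


REGISTRY = {
    "rw": rw_evolution,
    "go_nogo_softmax": go_nogo_softmax,
    "dcm_bilinear": dcm_evolution,
    "qlearn_dynamic_rate": qlearn_dynamic_rate_evolution,
    "qlearn_fixed_rate": qlearn_fixed_rate_evolution,
    "qlearn_random_walk_rate": qlearn_random_walk_rate_evolution,
    "q_diff_softmax": q_diff_softmax,
    "hrf_conv": hrf_conv_observation,
    "lorenz": lorenz_evolution,
    "vanderpol": vanderpol_evolution,
    "double_well": double_well_evolution,
    "linear_feedback": linear_feedback_evolution,
    "sigmoid_classifier": sigmoid_classifier_observation,
    "identity": identity_observation,
    "linear": linear_observation,
    "rfx_glm_f": rfx_glm_evolution,
    "rfx_glm_g": rfx_glm_observation,
}
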