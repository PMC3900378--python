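"""Seeded fixture generators regenerating every demo's inputs.

Each builder returns an in-memory :class:`Fixture` bundle (datasets, inputs,
candidate models with their priors/options, and the ground truth used to
generate the data); :func:`fixture` optionally writes the bundle to disk as
CSV/JSON.  All randomness flows through one generator seeded from the call,
so bundles are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, Optional

import numpy as np

from .core import (
    GammaPrior,
    GaussianPrior,
    InversionOptions,
    ModelSpec,
    PriorBundle,
    TimeSeriesData,
)
from .models import (
    dcm_evolution,
    go_nogo_softmax,
    hrf_conv_observation,
    identity_observation,
    linear_feedback_evolution,
    linear_observation,
    lorenz_evolution,
    q_diff_softmax,
    qlearn_dynamic_rate_evolution,
    qlearn_fixed_rate_evolution,
    qlearn_random_walk_rate_evolution,
    rw_evolution,
    sigmoid,
    sigmoid_classifier_observation,
)
from .simulate import add_noise_snr, simulate
from .transforms import augment_ar1, embed_delays, with_microtime

__all__ = ["Fixture", "fixture", "FIXTURES"]

_EMPTY = GaussianPrior(np.zeros(0), np.zeros((0, 0)))


def _fixed(v) -> GaussianPrior:
    v = np.atleast_1d(np.asarray(v, dtype=float))
    return GaussianPrior(v, np.zeros((v.size, v.size)))


@dataclass
class Fixture:
    name: str
    seed: int
    datasets: Dict[str, TimeSeriesData] = field(default_factory=dict)
    inputs: Dict[str, np.ndarray] = field(default_factory=dict)
    models: Dict[str, tuple] = field(default_factory=dict)  # (spec, priors, options)
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# asymmetric Rescorla-Wagner go/no-go experiment

def _rw_spec(variant: str, source: str) -> tuple:
    n_th = {"utility": 3, "learning": 3, "both": 4, "none": 2}[variant]
    pm = {"utility": [0.0, 1.0, 1.0], "learning": [0.0, 0.0, 1.0],
          "both": [0.0, 0.0, 1.0, 1.0], "none": [0.0, 1.0]}[variant]
    pv = {"utility": [2.0, 1.0, 1.0], "learning": [2.0, 2.0, 1.0],
          "both": [2.0, 2.0, 1.0, 1.0], "none": [2.0, 1.0]}[variant]
    if source == "binary":
        spec = ModelSpec(
            f=rw_evolution, g=go_nogo_softmax, n=1, n_theta=n_th, n_phi=1,
            source="binary", extras={"variant": variant, "gated": True},
        )
        phi_prior = GaussianPrior([0.0], np.eye(1))
    else:
        spec = ModelSpec(
            f=rw_evolution, g=identity_observation, n=1, n_theta=n_th, n_phi=0,
            source="continuous", extras={"variant": variant, "gated": True},
        )
        phi_prior = _EMPTY
    priors = PriorBundle(
        theta=GaussianPrior(np.array(pm), np.diag(pv)),
        phi=phi_prior,
        x0=_fixed([0.0]),
    )
    return spec, priors, InversionOptions(max_iter=32, tol_dF=1e-3)


def build_asym_rw(seed: int, n_trials: int = 160) -> Fixture:
    """Go/no-go reinforcement learning under utility asymmetry.

    The simulated agent learns the 'go' value with a single learning rate
    (alpha = 0.5) but weighs gains twice as much as losses (b+ = 2, b- = 1);
    choices follow a softmax with a no-go bias.  Feedback on 'go' trials is
    sampled 2/5 positive, 2/5 negative, 1/5 neutral.  Vegetative ('value')
    data are the true values plus noise at SNR = 1 dB.
    """
    rng = np.random.default_rng(seed)
    alpha, bp, bm, bias = 0.5, 2.0, 1.0, 0.3
    x = 0.0
    fb_hist = np.zeros(n_trials)
    go_hist = np.zeros(n_trials)
    values = np.zeros(n_trials)
    choices = np.zeros(n_trials)
    for t in range(n_trials):
        values[t] = x  # value driving the choice (updated through trial t-1)
        p_go = sigmoid(x - bias)
        go = float(rng.random() < p_go)
        if go:
            fb = rng.choice([1.0, -1.0, 0.0], p=[0.4, 0.4, 0.2])
            util = bp * fb if fb > 0 else (bm * fb if fb < 0 else 0.0)
            x = x + alpha * (util - x)
        else:
            fb = 0.0
        choices[t] = go
        fb_hist[t] = fb
        go_hist[t] = go
    # inputs lagged by one trial: the value used for choice t was updated
    # with the outcome of trial t-1
    u = np.zeros((2, n_trials))
    u[0, 1:] = fb_hist[:-1]
    u[1, 1:] = go_hist[:-1]
    y_choice = TimeSeriesData(y=choices[None, :], u=u)
    y_value = TimeSeriesData(
        y=add_noise_snr(values, 1.0, rng)[None, :], u=u
    )
    fx = Fixture("asymRW", seed)
    fx.datasets = {"choice": y_choice, "value": y_value}
    fx.inputs = {"u": u}
    for variant in ("utility", "learning", "both", "none"):
        fx.models[f"choice_{variant}"] = _rw_spec(variant, "binary")
        fx.models[f"value_{variant}"] = _rw_spec(variant, "continuous")
    fx.meta = {
        "registry": {
            f"{d}_{v}": ("rw", "go_nogo_softmax" if d == "choice" else "identity")
            for d in ("choice", "value")
            for v in ("utility", "learning", "both", "none")
        },
        "truth": {"alpha": alpha, "b_plus": bp, "b_minus": bm, "bias": bias},
        "true_values": values,
        "families": {
            "utility": {"utility": 1, "learning": 0, "both": 1, "none": 0},
            "learning": {"utility": 0, "learning": 1, "both": 1, "none": 0},
        },
    }
    return fx


# ---------------------------------------------------------------------------
# binary classification (H1 vs H0)

def build_bin(seed: int, n_trials: int = 64, n_features: int = 2) -> Fixture:
    """Static sigmoid classification: H1 has a non-zero feature mapping A,
    H0 none (intercept only)."""
    rng = np.random.default_rng(seed)
    u = rng.standard_normal((n_features, n_trials))
    A_true = np.array([1.5, -1.0])[:n_features]
    spec = ModelSpec(
        f=None, g=sigmoid_classifier_observation, n=0, n_theta=0,
        n_phi=n_features + 1, source="binary",
    )
    p1 = sigmoid(A_true @ u)
    y1 = (rng.random(n_trials) < p1).astype(float)
    y0 = (rng.random(n_trials) < 0.5).astype(float)
    cov_h1 = np.eye(n_features + 1)
    cov_h0 = np.zeros((n_features + 1, n_features + 1))
    cov_h0[-1, -1] = 1.0
    priors_h1 = PriorBundle(
        theta=_EMPTY, phi=GaussianPrior(np.zeros(n_features + 1), cov_h1), x0=_EMPTY
    )
    priors_h0 = PriorBundle(
        theta=_EMPTY, phi=GaussianPrior(np.zeros(n_features + 1), cov_h0), x0=_EMPTY
    )
    opts = InversionOptions(max_iter=32, tol_dF=1e-4)
    fx = Fixture("bin", seed)
    fx.datasets = {
        "h1": TimeSeriesData(y=y1[None, :], u=u),
        "h0": TimeSeriesData(y=y0[None, :], u=u),
    }
    fx.inputs = {"u": u}
    fx.models = {"H1": (spec, priors_h1, opts), "H0": (spec, priors_h0, opts)}
    fx.meta = {
        "A_true": A_true,
        "registry": {m: (None, "sigmoid_classifier") for m in ("H1", "H0")},
    }
    return fx


# ---------------------------------------------------------------------------
# random-effects GLM (group mean inference)

def build_rfx(seed: int, S: int = 32, reps: int = 4, h1: bool = True) -> Fixture:
    """Two-level mixed-effects model: subject effects scattered around a group
    mean (0.5 under H1, 0 under H0; between-subject sd 0.5, noise sd 1)."""
    from .models import rfx_glm_spec

    rng = np.random.default_rng(seed)
    mu_true = 0.5 if h1 else 0.0
    effects = mu_true + 0.5 * rng.standard_normal(S)
    y = np.repeat(effects, reps) + rng.standard_normal(S * reps)
    spec_h1, priors_h1 = rfx_glm_spec(S)
    spec_h0, priors_h0 = rfx_glm_spec(S, h0=True)
    spec_h1.extras["reps"] = reps
    spec_h0.extras["reps"] = reps
    opts = InversionOptions(lag_k=0, max_iter=24, tol_dF=1e-3)
    fx = Fixture("rfx", seed)
    fx.datasets = {"y": TimeSeriesData(y=y[:, None])}
    fx.models = {
        "H1": (spec_h1, priors_h1, opts),
        "H0": (spec_h0, priors_h0, opts),
    }
    fx.meta = {
        "mu_true": mu_true,
        "effects": effects,
        "registry": {m: ("rfx_glm_f", "rfx_glm_g") for m in ("H1", "H0")},
    }
    return fx


# ---------------------------------------------------------------------------
# group BMS over two GLM populations

def build_bmc4glm(
    seed: int, S_per_group: int = 32, n_obs: int = 64, n_factors: int = 4
) -> Fixture:
    """Two groups of subjects under a 'full' (all factors) vs 'reduced'
    (half of the factors) GLM, at SNR = 0 dB."""
    rng = np.random.default_rng(seed)
    half = n_factors // 2
    subjects = []
    for grp, active in (("full", n_factors), ("reduced", half)):
        for _ in range(S_per_group):
            X = rng.standard_normal((n_obs, n_factors))
            beta = np.zeros(n_factors)
            beta[:active] = rng.standard_normal(active)
            signal = X @ beta
            y = add_noise_snr(signal, 0.0, rng)
            subjects.append({"group": grp, "X": X, "y": y, "beta": beta})
    spec = ModelSpec(
        f=None, g=linear_observation, n=0, n_theta=0, n_phi=n_factors,
        source="continuous",
    )
    cov_full = np.eye(n_factors)
    cov_red = np.zeros((n_factors, n_factors))
    cov_red[:half, :half] = np.eye(half)
    mk = lambda cov: PriorBundle(
        theta=_EMPTY, phi=GaussianPrior(np.zeros(n_factors), cov), x0=_EMPTY,
        noise_precision=GammaPrior(1.0, 1.0),
    )
    opts = InversionOptions(max_iter=32, tol_dF=1e-5)
    fx = Fixture("bmc4glm", seed)
    fx.models = {"full": (spec, mk(cov_full), opts), "reduced": (spec, mk(cov_red), opts)}
    fx.meta = {
        "subjects": subjects, "n_factors": n_factors, "half": half,
        "registry": {m: (None, "linear") for m in ("full", "reduced")},
    }
    return fx


# ---------------------------------------------------------------------------
# Lorenz system (stochastic vs deterministic)

def build_lorenz(seed: int, T: int = 120) -> Fixture:
    """Lorenz system with state noise, observed in all three coordinates."""
    params = np.array([10.0, 28.0, 8.0 / 3.0])
    x0 = np.array([-5.9, -5.6, 24.5])
    base = ModelSpec(
        f=lorenz_evolution, g=identity_observation, n=3, n_theta=3, n_phi=0,
        source="continuous", dt=0.02, extras={"dt": 0.02},
    )
    spec = with_microtime(base, 2)
    data, traj = simulate(
        spec, params, [], x0, None, T=T,
        state_precision=50.0, noise_precision=4.0, seed=seed,
    )
    priors = PriorBundle(
        theta=_fixed(params),
        phi=_EMPTY,
        x0=GaussianPrior(x0, np.eye(3) * 1.0),
        state_precision=GammaPrior(1.0, 1.0),
        noise_precision=GammaPrior(1.0, 1.0),
    )
    opts = InversionOptions(lag_k=0, max_iter=8, tol_dF=0.05)
    fx = Fixture("lorenz", seed)
    fx.datasets = {"y": data}
    fx.models = {"lorenz": (spec, priors, opts)}
    fx.meta = {"traj": traj, "params": params, "x0": x0}
    return fx


# ---------------------------------------------------------------------------
# delayed linear feedback

def build_delays(seed: int, T: int = 80, delay: int = 2) -> Fixture:
    """Two-dimensional linear system with delayed cross-feedback; competing
    models assume the correct delay or none."""
    M = np.array([[0.9, -0.35], [0.35, 0.9]])
    tmap = [(0, 1), (1, 0)]
    x0 = np.array([2.0, 0.0])

    def mk_spec(D):
        s = ModelSpec(
            f=linear_feedback_evolution, g=identity_observation, n=2,
            n_theta=2, n_phi=0, source="continuous",
            extras={"M": M.copy(), "theta_map": tmap},
            delay_matrix=np.array([[0, D], [D, 0]]),
        )
        emb = embed_delays(s)
        hist = np.tile(x0, emb.n // 2)
        priors = PriorBundle(
            theta=GaussianPrior([0.0, 0.0], np.eye(2) * 0.5),
            phi=_EMPTY,
            x0=_fixed(hist),
            noise_precision=GammaPrior(1.0, 1.0),
        )
        return emb, priors, InversionOptions(max_iter=24, tol_dF=1e-3)

    spec_true, priors_true, opts = mk_spec(delay)
    data, traj = simulate(
        spec_true, np.array([-0.35, 0.35]), [], np.tile(x0, delay + 1), None,
        T=T, state_precision=np.inf, noise_precision=50.0, seed=seed,
    )
    fx = Fixture("delays", seed)
    fx.datasets = {"y": data}
    fx.models = {"delayed": mk_spec(delay), "nondelayed": mk_spec(0)}
    fx.meta = {"delay": delay, "M": M, "traj": traj}
    return fx


# ---------------------------------------------------------------------------
# AR(1) state noise

def build_ar1(seed: int, T: int = 160, decay: float = 0.8) -> Fixture:
    """Scalar linear system driven by AR(1) state noise; competing models
    assume auto-correlated or white drive."""
    base = ModelSpec(
        f=linear_feedback_evolution, g=identity_observation, n=1,
        n_theta=0, n_phi=0, source="continuous", extras={"M": [[0.5]]},
    )
    spec_ar, Q_ar = augment_ar1(base, decay)

    def g_first(x, ph, u, ex):
        return np.atleast_1d(x[0])

    spec_ar.g = g_first
    data, traj = simulate(
        spec_ar, [], [], np.zeros(2), None, T=T,
        state_precision=2.0, noise_precision=25.0, seed=seed,
        cov_structure=Q_ar,
    )
    priors_ar = PriorBundle(
        theta=_EMPTY, phi=_EMPTY, x0=_fixed(np.zeros(2)),
        state_precision=GammaPrior(1.0, 1.0),
        noise_precision=GammaPrior(1.0, 1.0),
        state_noise_cov_structure=Q_ar,
    )
    priors_white = PriorBundle(
        theta=_EMPTY, phi=_EMPTY, x0=_fixed(np.zeros(1)),
        state_precision=GammaPrior(1.0, 1.0),
        noise_precision=GammaPrior(1.0, 1.0),
    )
    # the AR(1) drive reaches the observed block one step late; lag 4 keeps
    # the lagged statistics consistent under the down-weighted x-block noise
    opts = InversionOptions(lag_k=4, max_iter=12, tol_dF=0.02)
    fx = Fixture("ar1", seed)
    fx.datasets = {"y": data}
    fx.models = {
        "ar1": (spec_ar, priors_ar, opts),
        "white": (base, priors_white, opts),
    }
    fx.meta = {"decay": decay, "traj": traj}
    return fx


# ---------------------------------------------------------------------------
# hemodynamic response / microtime

def build_hrf(seed: int, T: int = 120) -> Fixture:
    """One-region neural dynamics driven by a boxcar input, observed through
    a double-gamma hemodynamic convolution; inverted at slow vs fast
    microtime resolution."""
    u = np.zeros((1, T))
    for b in range(0, T, 20):
        u[0, b: b + 10] = 1.0
    extras = {
        "A": [[-0.8]], "C": [[1.0]], "dt": 1.0,
        "theta_map": [("A", (0, 0)), ("C", (0, 0))],
        "kernel_length": 16, "kernel_dt": 1.0,
    }

    def mk(n_micro):
        base = ModelSpec(
            f=dcm_evolution, g=hrf_conv_observation, n=1, n_theta=2, n_phi=1,
            source="continuous", dt=1.0, extras=dict(extras),
            g_takes_trajectory=True,
        )
        s = with_microtime(base, n_micro) if n_micro > 1 else base
        priors = PriorBundle(
            theta=GaussianPrior([-0.5, 0.5], np.eye(2) * 0.25),
            phi=GaussianPrior([1.0], np.eye(1) * 0.25),
            x0=_fixed([0.0]),
            noise_precision=GammaPrior(1.0, 1.0),
        )
        return s, priors, InversionOptions(max_iter=24, tol_dF=1e-3)

    spec_fine, _, _ = mk(8)
    data, traj = simulate(
        spec_fine, np.array([-0.8, 1.0]), np.array([1.0]), np.zeros(1), u,
        state_precision=np.inf, noise_precision=100.0, seed=seed,
    )
    fx = Fixture("hrf", seed)
    fx.datasets = {"y": data}
    fx.inputs = {"u": u}
    fx.models = {"micro1": mk(1), "micro4": mk(4)}
    fx.meta = {"traj": traj}
    return fx


# ---------------------------------------------------------------------------
# online DCM design optimization

def dcm_pair(dt: float = 1.0, n_micro: int = 2):
    """The two-node network comparison: photic drives V1 which feeds V5;
    model m1 lets attention modulate the V1->V5 connection, m2 does not."""
    extras = {
        "A": [[-1.0, 0.0], [0.4, -1.0]],
        "B": [[[0.0, 0.0], [0.0, 0.0]], [[0.0, 0.0], [0.0, 0.0]]],
        "C": [[1.0, 0.0], [0.0, 0.0]],
        "dt": dt,
        "kernel_length": 16, "kernel_dt": dt, "gains": [1.0, 1.0],
    }

    def mk(with_mod):
        ex = {k: (np.array(v, dtype=float) if isinstance(v, list) else v)
              for k, v in extras.items()}
        tmap = [("A", (1, 0))] + ([("B", (1, 1, 0))] if with_mod else [])
        ex["theta_map"] = tmap
        base = ModelSpec(
            f=dcm_evolution, g=hrf_conv_observation, n=2,
            n_theta=len(tmap), n_phi=0, source="continuous", dt=dt,
            extras=ex, g_takes_trajectory=True,
        )
        s = with_microtime(base, n_micro) if n_micro > 1 else base
        pm = [0.2] + ([0.0] if with_mod else [])
        pv = [0.25] * len(tmap)
        priors = PriorBundle(
            theta=GaussianPrior(np.array(pm), np.diag(pv)),
            phi=_EMPTY, x0=_fixed(np.zeros(2)),
            noise_precision=GammaPrior(10.0, 1.0),
        )
        return s, priors, InversionOptions(max_iter=16, tol_dF=1e-3)

    return mk(True), mk(False)


def build_dcm_online(seed: int, n_blocks: int = 10) -> Fixture:
    """Fixture for the online design-optimization experiment: true network
    has an attentional modulation (b = 0.4) of the V1->V5 connection; each
    block is 16 s of photic stimulation plus 16 s of rest, with or without
    attention."""
    m1, m2 = dcm_pair()
    fx = Fixture("dcm_online", seed)
    fx.models = {"m1": m1, "m2": m2}
    fx.meta = {
        "n_blocks": n_blocks,
        "theta_true": np.array([0.4, 0.4]),
        "noise_precision": 16.0,
        "block_on": 16,
        "block_off": 16,
    }
    return fx


# ---------------------------------------------------------------------------
# dynamic learning rate bandit

def build_dyn_learning_rate(
    seed: int, n_trials: int = 400, reversal_every: int = 50
) -> Fixture:
    """Volatile two-armed bandit with contingency reversals every fifty
    trials.  Choices are simulated from a Q-learner whose learning rate
    transiently accelerates after each reversal (a scripted stand-in for a
    volatility-tracking agent); the candidate models are the stochastic
    random-walk-rate model, the standard fixed-rate Q-learner, and the
    augmented (instability-driven) Q-learner.
    """
    rng = np.random.default_rng(seed)
    winning = ((np.arange(n_trials) // reversal_every) % 2).astype(float)
    inst = np.zeros(n_trials)
    inst[1:] = (np.diff(winning) != 0).astype(float)
    omega_true, decay_true_raw, beta = 3.0, 0.0, 1.5
    p_reward = 0.9
    r0 = -1.0
    x = np.array([0.0, 0.0, r0, 0.0])
    choices = np.zeros(n_trials)
    fbs = np.zeros(n_trials)
    rates = np.zeros(n_trials)
    for t in range(n_trials):
        u_t = np.array([
            choices[t - 1] if t else 0.0,
            fbs[t - 1] if t else 0.0,
            inst[t],
        ])
        x = qlearn_dynamic_rate_evolution(
            x, np.array([omega_true, decay_true_raw]), u_t, {}
        )
        rates[t] = sigmoid(x[2])
        p2 = sigmoid(beta * (x[1] - x[0]))
        c = float(rng.random() < p2)
        correct = c == winning[t]
        fb = 1.0 if rng.random() < (p_reward if correct else 1 - p_reward) else -1.0
        choices[t] = c
        fbs[t] = fb
    u = np.zeros((3, n_trials))
    u[0, 1:] = choices[:-1]
    u[1, 1:] = fbs[:-1]
    u[2, :] = inst
    data = TimeSeriesData(y=choices[None, :], u=u)

    obs_extras = {"beta": beta}
    # stochastic random-walk learning rate: rate-state noise precision set a
    # hundred times smaller than the action values'
    Q = np.diag([0.01, 0.01, 1.0])
    spec_rw = ModelSpec(
        f=qlearn_random_walk_rate_evolution, g=q_diff_softmax, n=3,
        n_theta=0, n_phi=0, source="binary", extras=dict(obs_extras),
    )
    priors_rw = PriorBundle(
        theta=_EMPTY, phi=_EMPTY,
        x0=GaussianPrior([0.0, 0.0, r0], np.diag([0.0, 0.0, 0.5])),
        state_precision=GammaPrior(2.0, 0.02),
        state_noise_cov_structure=Q,
    )
    # overall state-noise level held fixed (the 100x precision ratio between
    # value and rate blocks is carried by Q); lag 3 lets choice data a few
    # trials ahead inform the rate state
    opts_rw = InversionOptions(
        lag_k=3, max_iter=8, tol_dF=0.05, fixed_state_precision=2.0
    )

    spec_fixed = ModelSpec(
        f=qlearn_fixed_rate_evolution, g=q_diff_softmax, n=2,
        n_theta=1, n_phi=0, source="binary", extras=dict(obs_extras),
    )
    priors_fixed = PriorBundle(
        theta=GaussianPrior([-1.0], np.eye(1) * 2.0),
        phi=_EMPTY, x0=_fixed([0.0, 0.0]),
    )
    spec_aug = ModelSpec(
        f=qlearn_dynamic_rate_evolution, g=q_diff_softmax, n=4,
        n_theta=2, n_phi=0, source="binary", extras=dict(obs_extras),
    )
    priors_aug = PriorBundle(
        theta=GaussianPrior([0.0, 0.0], np.diag([4.0, 4.0])),
        phi=_EMPTY,
        x0=GaussianPrior([0.0, 0.0, r0, 0.0], np.diag([0.0, 0.0, 0.5, 0.0])),
    )
    opts_det = InversionOptions(max_iter=24, tol_dF=1e-3)
    fx = Fixture("dyn_learning_rate", seed)
    fx.datasets = {"choices": data}
    fx.inputs = {"u": u}
    fx.models = {
        "stochastic_rate": (spec_rw, priors_rw, opts_rw),
        "qlearn_standard": (spec_fixed, priors_fixed, opts_det),
        "qlearn_augmented": (spec_aug, priors_aug, opts_det),
    }
    fx.meta = {
        "winning": winning,
        "instability": inst,
        "rates": rates,
        "omega_true": omega_true,
        "registry": {
            "stochastic_rate": ("qlearn_random_walk_rate", "q_diff_softmax"),
            "qlearn_standard": ("qlearn_fixed_rate", "q_diff_softmax"),
            "qlearn_augmented": ("qlearn_dynamic_rate", "q_diff_softmax"),
        },
    }
    return fx


# ---------------------------------------------------------------------------

FIXTURES: Dict[str, Callable[[int], Fixture]] = {
    "asymRW": build_asym_rw,
    "bin": build_bin,
    "rfx": build_rfx,
    "bmc4glm": build_bmc4glm,
    "lorenz": build_lorenz,
    "delays": build_delays,
    "ar1": build_ar1,
    "hrf": build_hrf,
    "dcm_online": build_dcm_online,
    "dyn_learning_rate": build_dyn_learning_rate,
}


def fixture(name: str, seed: int, out_dir: Optional[str] = None) -> Fixture:
    """Build (and optionally write to disk) the named demo bundle."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(FIXTURES)}")
    fx = FIXTURES[name](seed)
    if out_dir is not None:
        from . import io as vio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for dname, data in fx.datasets.items():
            vio.write_timeseries_csv(out / f"data_{dname}.csv", data)
        for uname, u in fx.inputs.items():
            vio.write_matrix_csv(out / f"inputs_{uname}.csv", u)
        registry_names = fx.meta.get("registry", {})
        for mname, (spec, priors, opts) in fx.models.items():
            vio.priors_to_json(out / f"priors_{mname}.json", priors)
            vio.options_to_json(out / f"options_{mname}.json", opts)
            if mname in registry_names:
                fname, gname = registry_names[mname]
                vio.spec_to_json(out / f"model_{mname}.json", spec, fname, gname)
    return fx
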