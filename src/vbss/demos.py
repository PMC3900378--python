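"""End-to-end demo experiments over the seeded fixtures.

Each ``run_demo`` entry regenerates its inputs via :mod:`vbss.fixtures`,
runs the relevant inversions/comparisons and returns a dictionary of numeric
results (optionally written to disk as JSON/CSV).  Monte-Carlo demos accept a
replicate count so desk-scale runs stay fast.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np

from .compare import family_posterior, group_bms, posterior_model_probs
from .core import GaussianPrior, GammaPrior, InversionOptions, PriorBundle, TimeSeriesData
from .design import block_design, online_design_step
from .diagnostics import residual_acf, volterra_kernels
from .fixtures import fixture
from .inversion import invert, invert_deterministic
from .inversion.engine import deterministic_trajectory, predict_observations
from .models import sigmoid

__all__ = ["run_demo", "DEMOS"]


def _subseed(seed: int, i: int) -> int:
    return (seed * 1009 + 7919 * i + 1) % (2**31 - 1)


# ---------------------------------------------------------------------------

def demo_asym_rw(seed: int, **kw) -> dict:
    """Family inference over asymmetric-utility / asymmetric-learning RW
    models, given either choice (binary) or value (continuous) data."""
    fx = fixture("asymRW", seed)
    variants = ("utility", "learning", "both", "none")
    out = {}
    for dname in ("choice", "value"):
        F = []
        for v in variants:
            spec, priors, opts = fx.models[f"{dname}_{v}"]
            _, rep = invert_deterministic(fx.datasets[dname], spec, priors, opts)
            F.append(rep.free_energy)
        probs = posterior_model_probs(np.array(F))
        fam_u = family_posterior(probs, [1, 0, 1, 0])  # (no, yes) sorted labels
        fam_l = family_posterior(probs, [0, 1, 1, 0])
        out[f"{dname}_free_energies"] = F
        out[f"{dname}_model_probs"] = probs.tolist()
        out[f"{dname}_family_utility_yes"] = float(fam_u[1])
        out[f"{dname}_family_learning_yes"] = float(fam_l[1])
    return out


def demo_lorenz(seed: int, **kw) -> dict:
    """Stochastic vs deterministic inversion of noisy Lorenz data."""
    fx = fixture("lorenz", seed)
    spec, priors, opts = fx.models["lorenz"]
    data = fx.datasets["y"]
    post_s, rep_s = invert(data, spec, priors, opts)
    _, rep_d = invert_deterministic(data, spec, priors, opts)
    acf_d, band = residual_acf(rep_d.residuals, max_lag=20)
    acf_s, _ = residual_acf(rep_s.residuals, max_lag=20)
    return {
        "F_stochastic": rep_s.free_energy,
        "F_deterministic": rep_d.free_energy,
        "dF": rep_s.free_energy - rep_d.free_energy,
        "fit_stochastic": rep_s.fit["variance_explained"],
        "fit_deterministic": rep_d.fit["variance_explained"],
        "acf_band": band,
        "acf1_deterministic": float(np.abs(acf_d[:, 1]).max()),
        "acf1_stochastic": float(np.abs(acf_s[:, 1]).max()),
    }


def demo_delays(seed: int, **kw) -> dict:
    """Delayed vs non-delayed model comparison on delayed-feedback data."""
    fx = fixture("delays", seed)
    data = fx.datasets["y"]
    out = {}
    for name in ("delayed", "nondelayed"):
        spec, priors, opts = fx.models[name]
        _, rep = invert_deterministic(data, spec, priors, opts)
        out[f"F_{name}"] = rep.free_energy
        out[f"fit_{name}"] = rep.fit["variance_explained"]
    out["dF"] = out["F_delayed"] - out["F_nondelayed"]
    return out


def demo_ar1(seed: int, **kw) -> dict:
    """Auto-correlated vs white state-noise comparison.

    Reports one-step innovation autocorrelations: the white-noise model's
    innovations inherit the unmodelled AR(1) drive correlation, the AR
    model's are close to white.
    """
    from .diagnostics import one_step_innovations
    from .core import validate

    fx = fixture("ar1", seed)
    data = fx.datasets["y"]
    out = {}
    for name in ("ar1", "white"):
        spec, priors, opts = fx.models[name]
        problem = validate(spec, data, priors)
        post, rep = invert(data, spec, priors, opts)
        innov = one_step_innovations(problem, post)
        acf, band = residual_acf(innov, max_lag=10)
        out[f"F_{name}"] = rep.free_energy
        out[f"acf1_{name}"] = float(acf[0, 1])
        out["acf_band"] = band
    out["dF"] = out["F_ar1"] - out["F_white"]
    return out


def demo_hrf(seed: int, **kw) -> dict:
    """Microtime-resolution effect on a convolution (hemodynamic) model."""
    from .diagnostics import posterior_correlation

    fx = fixture("hrf", seed)
    data = fx.datasets["y"]
    out = {}
    for name in ("micro1", "micro4"):
        spec, priors, opts = fx.models[name]
        post, rep = invert_deterministic(data, spec, priors, opts)
        R = posterior_correlation(post)
        off = np.abs(R[np.triu_indices_from(R, 1)])
        out[f"F_{name}"] = rep.free_energy
        out[f"fit_{name}"] = rep.fit["variance_explained"]
        out[f"max_offdiag_corr_{name}"] = float(off.max()) if off.size else 0.0
    return out


def demo_bin(seed: int, n_reps: int = 32, **kw) -> dict:
    """H1 vs H0 sigmoid classification: log Bayes factors and accuracy over
    Monte-Carlo replicates."""
    lbf_h1, lbf_h0, acc = [], [], []
    for i in range(n_reps):
        fx = fixture("bin", _subseed(seed, i))
        res = {}
        for dname in ("h1", "h0"):
            F = {}
            for mname in ("H1", "H0"):
                spec, priors, opts = fx.models[mname]
                _, rep = invert_deterministic(fx.datasets[dname], spec, priors, opts)
                F[mname] = rep.free_energy
                if dname == "h1" and mname == "H1":
                    acc.append(rep.fit["balanced_accuracy"])
            res[dname] = F["H1"] - F["H0"]
        lbf_h1.append(res["h1"])
        lbf_h0.append(res["h0"])
    return {
        "mean_log_bf_h1_data": float(np.mean(lbf_h1)),
        "mean_log_bf_h0_data": float(np.mean(lbf_h0)),
        "mean_balanced_accuracy_h1": float(np.mean(acc)),
        "n_reps": n_reps,
    }


def demo_rfx(seed: int, n_reps: int = 32, **kw) -> dict:
    """Random-effects group-mean inference: posterior sign recovery and H1/H0
    model comparison under both generative regimes."""
    from .fixtures import build_rfx

    lbf_h1, lbf_h0, means_h1, means_h0 = [], [], [], []
    for i in range(n_reps):
        for h1 in (True, False):
            fx = build_rfx(_subseed(seed, 2 * i + int(h1)), h1=h1)
            data = fx.datasets["y"]
            F = {}
            gm = None
            for mname in ("H1", "H0"):
                spec, priors, opts = fx.models[mname]
                post, rep = invert(data, spec, priors, opts)
                F[mname] = rep.free_energy
                if mname == "H1":
                    gm = float(post.theta.mean[0])
            if h1:
                lbf_h1.append(F["H1"] - F["H0"])
                means_h1.append(gm)
            else:
                lbf_h0.append(F["H1"] - F["H0"])
                means_h0.append(gm)
    return {
        "mean_log_bf_h1_data": float(np.mean(lbf_h1)),
        "mean_log_bf_h0_data": float(np.mean(lbf_h0)),
        "sign_recovery_h1": float(np.mean(np.sign(means_h1) > 0)),
        "mean_group_mean_h1": float(np.mean(means_h1)),
        "mean_group_mean_h0": float(np.mean(means_h0)),
        "n_reps": n_reps,
    }


def demo_bmc4glm(seed: int, **kw) -> dict:
    """Random-effects group BMS over full vs reduced GLM populations."""
    fx = fixture("bmc4glm", seed)
    spec = fx.models["full"][0]
    out = {}
    evid = {"full": [], "reduced": []}
    for subj in fx.meta["subjects"]:
        data = TimeSeriesData(y=subj["y"][None, :], u=subj["X"].T)
        row = []
        for mname in ("full", "reduced"):
            _, priors, opts = fx.models[mname]
            _, rep = invert_deterministic(data, spec, priors, opts)
            row.append(rep.free_energy)
        evid[subj["group"]].append(row)
    acc_all = []
    for gi, grp in enumerate(("full", "reduced")):
        L = np.array(evid[grp])
        res = group_bms(L, seed=_subseed(seed, 99))
        correct = res.attributions[:, gi]
        acc_all.extend((correct > 0.5).astype(float).tolist())
        out[f"exceedance_{grp}"] = res.exceedance.tolist()
        out[f"expected_freq_{grp}"] = res.expected_frequencies.tolist()
        out[f"attribution_accuracy_{grp}"] = float(np.mean(correct > 0.5))
        out[f"mean_log_bf_{grp}"] = float(np.mean(L[:, 0] - L[:, 1]))
    out["attribution_accuracy"] = float(np.mean(acc_all))
    return out


def demo_dcm_online(seed: int, n_blocks: int = 10, **kw) -> dict:
    """Online design optimization for the two-node attention-modulation
    comparison: before each block the candidate with the lower
    Laplace-Chernoff risk is played, data are simulated under the true
    (modulated) network, and both models are re-inverted."""
    fx = fixture("dcm_online", seed)
    rng = np.random.default_rng(seed)
    spec1, priors1, opts1 = fx.models["m1"]
    spec2, priors2, opts2 = fx.models["m2"]
    theta_true = fx.meta["theta_true"]
    nprec = fx.meta["noise_precision"]
    L = fx.meta["block_on"] + fx.meta["block_off"]
    cand_att = block_design(1, [0], fx.meta["block_on"], fx.meta["block_off"])
    cand_no = block_design(1, [], fx.meta["block_on"], fx.meta["block_off"])
    u_hist = np.zeros((2, 0))
    y = np.zeros((2, 0))
    score1, score2 = priors1, priors2
    effs, att_chosen, logbf, risks = [], [], [], []
    for b in range(n_blocks):
        step = online_design_step(
            [cand_att, cand_no], [(spec1, score1), (spec2, score2)],
            history_u=u_hist if u_hist.size else None,
        )
        chosen = cand_att if step.index == 0 else cand_no
        att_chosen.append(step.index == 0)
        effs.append(step.efficiency)
        risks.append(step.risks.tolist())
        u_hist = np.concatenate([u_hist, chosen], axis=1)
        T = u_hist.shape[1]
        xm = deterministic_trajectory(spec1, theta_true, np.zeros(2), u_hist, T)
        clean = predict_observations(spec1, xm, np.zeros(0), u_hist, T)
        seg = clean[:, T - L:] + rng.standard_normal((2, L)) / np.sqrt(nprec)
        y = np.concatenate([y, seg], axis=1)
        data = TimeSeriesData(y=y, u=u_hist)
        post1, rep1 = invert_deterministic(data, spec1, priors1, opts1)
        post2, rep2 = invert_deterministic(data, spec2, priors2, opts2)
        logbf.append(rep1.free_energy - rep2.free_energy)
        score1 = PriorBundle(
            theta=GaussianPrior(post1.theta.mean, post1.theta.covariance),
            phi=priors1.phi, x0=priors1.x0,
            noise_precision=GammaPrior(
                post1.noise_precision.a, post1.noise_precision.b
            ),
        )
        score2 = PriorBundle(
            theta=GaussianPrior(post2.theta.mean, post2.theta.covariance),
            phi=priors2.phi, x0=priors2.x0,
            noise_precision=GammaPrior(
                post2.noise_precision.a, post2.noise_precision.b
            ),
        )
    u_corr = float(np.corrcoef(u_hist[0], u_hist[1])[0, 1])
    return {
        "efficiency_trace": effs,
        "attention_chosen": [bool(a) for a in att_chosen],
        "log_bf_trace": logbf,
        "risks": risks,
        "final_log_bf": logbf[-1],
        "input_correlation": u_corr,
        "modulation_estimate": float(post1.theta.mean[1]),
    }


def demo_dyn_learning_rate(seed: int, n_reps: int = 20, **kw) -> dict:
    """Inversion diagnostics on the volatile bandit: Volterra kernel of the
    estimated learning-rate state on winning-action instability, and
    augmented vs standard Q-learning comparison over replicates."""
    fx = fixture("dyn_learning_rate", seed)
    data = fx.datasets["choices"]
    spec, priors, opts = fx.models["stochastic_rate"]
    post, rep = invert(data, spec, priors, opts)
    rate_state = post.states.means[2]
    inputs = np.vstack([
        data.u[0],                      # chosen action (lagged)
        fx.meta["winning"],             # winning action
        fx.meta["instability"],         # winning-action instability
    ])
    vk = volterra_kernels(rate_state[None, :], inputs, depth=16)
    inst_kernel = vk.kernels[0, 2]
    corr = float(np.corrcoef(sigmoid(rate_state), fx.meta["rates"])[0, 1])
    wins = 0
    dFs = []
    for i in range(n_reps):
        fxi = fixture("dyn_learning_rate", _subseed(seed, i))
        d = fxi.datasets["choices"]
        s_a, p_a, o_a = fxi.models["qlearn_augmented"]
        s_f, p_f, o_f = fxi.models["qlearn_standard"]
        _, rep_a = invert_deterministic(d, s_a, p_a, o_a)
        _, rep_f = invert_deterministic(d, s_f, p_f, o_f)
        dF = rep_a.free_energy - rep_f.free_energy
        dFs.append(dF)
        wins += dF > 0
    return {
        "instability_kernel": inst_kernel.tolist(),
        "instability_kernel_sum_0_4": float(inst_kernel[:5].sum()),
        "rate_volatility_correlation": corr,
        "augmented_win_fraction": wins / n_reps,
        "mean_dF_augmented_vs_standard": float(np.mean(dFs)),
        "n_reps": n_reps,
    }


def demo_rw_recovery(seed: int, n_reps: int = 100, n_trials: int = 200, **kw) -> dict:
    """Parameter-recovery study for the RW learning rate: simulate go/no-go
    choices with alpha drawn from its prior, re-estimate it (utility scale and
    softmax bias known), and report 95% credible-interval coverage and mean
    absolute error on the unconstrained scale."""
    from .core import GaussianPrior, InversionOptions, ModelSpec, PriorBundle
    from .models import go_nogo_softmax, rw_evolution

    covered, errs = [], []
    for i in range(n_reps):
        rng = np.random.default_rng(_subseed(seed, i))
        alpha_raw_true = rng.normal(0.0, 1.0)
        alpha = sigmoid(alpha_raw_true)
        x = 0.0
        fb = np.zeros(n_trials)
        go = np.zeros(n_trials)
        for t in range(n_trials):
            g = float(rng.random() < sigmoid(x))
            f = rng.choice([1.0, -1.0, 0.0], p=[0.4, 0.4, 0.2]) if g else 0.0
            if g:
                x = x + alpha * (f - x)
            fb[t], go[t] = f, g
        u = np.zeros((2, n_trials))
        u[0, 1:] = fb[:-1]
        u[1, 1:] = go[:-1]
        data = TimeSeriesData(y=go[None, :], u=u)
        spec = ModelSpec(
            f=rw_evolution, g=go_nogo_softmax, n=1, n_theta=2, n_phi=1,
            source="binary", extras={"variant": "none", "gated": True},
        )
        priors = PriorBundle(
            theta=GaussianPrior([0.0, 1.0], np.diag([1.0, 0.0])),  # beta known
            phi=GaussianPrior([0.0], np.zeros((1, 1))),            # bias known
            x0=GaussianPrior([0.0], np.zeros((1, 1))),
        )
        post, _ = invert_deterministic(
            data, spec, priors, InversionOptions(max_iter=32, tol_dF=1e-4)
        )
        m = post.theta.mean[0]
        sd = np.sqrt(post.theta.covariance[0, 0])
        covered.append((m - 1.96 * sd) <= alpha_raw_true <= (m + 1.96 * sd))
        errs.append(abs(m - alpha_raw_true))
    return {
        "coverage": float(np.mean(covered)),
        "mean_abs_error": float(np.mean(errs)),
        "prior_sd": 1.0,
        "n_reps": n_reps,
    }


def demo_design_rank(seed: int, n_mc: int = 2**12, **kw) -> dict:
    """Rank agreement between the Laplace-Chernoff risk and the Monte-Carlo
    model-selection error across eight 1-D designs (two fixed-parameter linear
    models predicting +/- u with unit noise)."""
    from math import erf

    from .core import GaussianPrior, ModelSpec, PriorBundle, GammaPrior
    from .design import chernoff_risk, prior_predictive
    from .models import linear_observation
    from scipy.stats import kendalltau

    designs = [0.1, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0]
    spec = ModelSpec(f=None, g=linear_observation, n=0, n_theta=0, n_phi=1)
    _E = GaussianPrior(np.zeros(0), np.zeros((0, 0)))

    def priors_for(sign):
        return PriorBundle(
            theta=_E, x0=_E,
            phi=GaussianPrior([float(sign)], np.zeros((1, 1))),
            noise_precision=GammaPrior(1.0, 1.0),
        )

    rng = np.random.default_rng(seed)
    risks, mc_err, exact_err = [], [], []
    for u_val in designs:
        u = np.array([[u_val]])
        p1 = prior_predictive(spec, priors_for(+1), u)
        p2 = prior_predictive(spec, priors_for(-1), u)
        risks.append(chernoff_risk(p1, p2))
        truth = rng.random(n_mc) < 0.5
        mu = np.where(truth, u_val, -u_val)
        y = mu + rng.standard_normal(n_mc)
        pick_m1 = np.abs(y - u_val) < np.abs(y + u_val)
        mc_err.append(float(np.mean(pick_m1 != truth)))
        exact_err.append(0.5 * (1 - erf(u_val / np.sqrt(2))))
    tau_mc = kendalltau(risks, mc_err).statistic
    tau_exact = kendalltau(risks, exact_err).statistic
    return {
        "designs": designs,
        "risks": risks,
        "mc_error": mc_err,
        "exact_error": exact_err,
        "kendall_tau_mc": float(tau_mc),
        "kendall_tau_exact": float(tau_exact),
        "n_mc": n_mc,
    }


DEMOS = {
    "asymRW": demo_asym_rw,
    "lorenz": demo_lorenz,
    "delays": demo_delays,
    "ar1": demo_ar1,
    "hrf": demo_hrf,
    "bin": demo_bin,
    "rfx": demo_rfx,
    "bmc4glm": demo_bmc4glm,
    "dcm_online": demo_dcm_online,
    "dyn_learning_rate": demo_dyn_learning_rate,
    "rw_recovery": demo_rw_recovery,
    "design_rank": demo_design_rank,
}


def run_demo(name: str, seed: int, out_dir: Optional[str] = None, **kw) -> dict:
    """Execute a demo end-to-end; optionally write results JSON to disk."""
    if name not in DEMOS:
        raise KeyError(f"unknown demo {name!r}; known: {sorted(DEMOS)}")
    res = DEMOS[name](seed, **kw)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / f"demo_{name}.json").write_text(json.dumps(res, indent=1))
    return res
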