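"""Registered model mappings: reductions, fixed points and recovery checks."""

import numpy as np
import pytest

import vbss
from vbss import GaussianPrior, InversionOptions, ModelSpec, PriorBundle, TimeSeriesData
from vbss.models import (
    dcm_evolution,
    go_nogo_softmax,
    hrf_kernel,
    hrf_observation,
    lorenz_evolution,
    qlearn_dynamic_rate_evolution,
    rfx_glm_spec,
    rw_evolution,
    sigmoid,
    sigmoid_classifier_observation,
)

EMPTY = GaussianPrior(np.zeros(0), np.zeros((0, 0)))


class TestRescorlaWagner:
    def test_zero_learning_rate_keeps_value(self):
        x = rw_evolution(np.array([0.4]), [-30.0, 1.0], [1.0], {"variant": "none"})
        assert abs(x[0] - 0.4) < 1e-8

    def test_full_update_reaches_utility(self):
        x = rw_evolution(np.array([-3.0]), [30.0, 1.0], [1.0], {"variant": "none"})
        assert abs(x[0] - 1.0) < 1e-8

    def test_asymmetric_utility_arithmetic(self):
        # alpha = 0.5, b+ = 2, u = +1: x = 0 + 0.5*(2 - 0) = 1
        x = rw_evolution(np.array([0.0]), [0.0, 2.0, 1.0], [1.0], {"variant": "utility"})
        assert abs(x[0] - 1.0) < 1e-12

    def test_geometric_fixed_point_convergence(self):
        alpha_raw, beta = 0.0, 1.5  # alpha = 0.5
        x = np.array([0.0])
        gaps = []
        for _ in range(8):
            x = rw_evolution(x, [alpha_raw, beta], [1.0], {"variant": "none"})
            gaps.append(abs(x[0] - beta))
        ratios = [b / a for a, b in zip(gaps, gaps[1:])]
        assert np.allclose(ratios, 0.5, atol=1e-10)

    def test_no_go_trials_freeze_learning_when_gated(self):
        x = rw_evolution(
            np.array([0.3]), [0.0, 1.0], [1.0, 0.0], {"variant": "none", "gated": True}
        )
        assert x[0] == 0.3


class TestGoNogoSoftmax:
    def test_indifference_at_bias(self):
        assert go_nogo_softmax(np.array([0.7]), [0.7], [], {})[0] == pytest.approx(0.5)

    def test_saturation(self):
        assert go_nogo_softmax(np.array([50.0]), [0.0], [], {})[0] == pytest.approx(1.0)

    def test_complementarity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x, b = rng.standard_normal(2) * 3
            p = go_nogo_softmax(np.array([x]), [b], [], {})[0]
            q = go_nogo_softmax(np.array([b]), [x], [], {})[0]
            assert p + q == pytest.approx(1.0, abs=1e-12)


class TestDCMEvolution:
    def test_null_field_keeps_state(self):
        x = np.array([0.3, -0.2])
        out = dcm_evolution(x, [], np.zeros(1), {"dt": 1.0})
        assert np.allclose(out, x)

    def test_linear_reduction_without_inputs(self):
        A = np.array([[-0.5, 0.2], [0.1, -0.3]])
        x = np.array([1.0, -1.0])
        out = dcm_evolution(x, [], np.zeros(0), {"A": A, "dt": 0.5})
        assert np.allclose(out, x + 0.5 * A @ x, atol=1e-12)

    def test_microtime_converges_to_exponential(self):
        from vbss.transforms import with_microtime

        spec = ModelSpec(
            f=dcm_evolution, g=lambda x, ph, u, ex: x.copy(),
            n=1, n_theta=0, n_phi=0, dt=1.0,
            extras={"A": [[-1.0]], "dt": 1.0},
        )
        errs = []
        for n_micro in (1, 4, 16):
            s = with_microtime(spec, n_micro)
            _, traj = vbss.simulate(s, [], [], np.ones(1), None, T=2)
            errs.append(abs(traj.x[0, 1] - np.exp(-2.0)))
        assert errs[0] > errs[1] > errs[2]


class TestHRF:
    def test_impulse_response_is_kernel(self):
        kern = hrf_kernel(16)
        neural = np.zeros((1, 40))
        neural[0, 0] = 1.0
        out = hrf_observation(neural, np.array([2.0]), kern)
        assert np.allclose(out[0, :16], 2.0 * kern)

    def test_zero_input_zero_output(self):
        out = hrf_observation(np.zeros((2, 30)), np.ones(2), hrf_kernel(16))
        assert np.allclose(out, 0.0)

    def test_superposition_of_impulses(self):
        kern = hrf_kernel(16)
        n1 = np.zeros((1, 50)); n1[0, 3] = 1.0
        n2 = np.zeros((1, 50)); n2[0, 20] = 1.0
        both = hrf_observation(n1 + n2, np.ones(1), kern)
        sep = hrf_observation(n1, np.ones(1), kern) + hrf_observation(n2, np.ones(1), kern)
        assert np.abs(both - sep).max() < 1e-10

    def test_kernel_longer_than_series_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            hrf_observation(np.zeros((1, 8)), np.ones(1), hrf_kernel(16))


class TestDynamicLearningRate:
    def test_zero_coupling_reduces_to_fixed_rate(self):
        x = np.array([0.2, -0.1, 0.5, 0.0])
        out = qlearn_dynamic_rate_evolution(x, [0.0, 0.0], [1.0, 1.0, 1.0], {})
        # rate state untouched, chosen value updated with sigmoid(0.5)
        assert out[2] == 0.5 and out[3] == 0.0
        assert out[1] == pytest.approx(-0.1 + sigmoid(0.5) * (1.0 + 0.1))

    def test_unchosen_value_unchanged(self):
        x = np.array([0.2, -0.1, 0.5, 0.0])
        out = qlearn_dynamic_rate_evolution(x, [1.0, 0.0], [0.0, 1.0, 0.0], {})
        assert out[1] == -0.1

    def test_impulse_response_rises_then_decays(self):
        omega, decay_raw = 1.5, 0.0
        x = np.array([0.0, 0.0, -2.0, 0.0])
        rates = []
        for t in range(12):
            inst = 1.0 if t == 3 else 0.0
            x = qlearn_dynamic_rate_evolution(x, [omega, decay_raw], [0.0, 0.0, inst], {})
            rates.append(sigmoid(x[2]))
        assert rates[3] > rates[2]  # jump at the pulse
        # derivative decays geometrically afterwards: increments shrink
        incs = np.diff(rates[3:])
        assert np.all(incs > 0)
        assert np.all(np.diff(incs) < 0)


class TestBenchmarkFields:
    def test_lorenz_fixed_point_at_origin(self):
        out = lorenz_evolution(np.zeros(3), [10.0, 28.0, 8 / 3], [], {"dt": 0.01})
        assert np.allclose(out, 0.0)

    def test_lorenz_nearby_trajectories_separate(self):
        spec = ModelSpec(
            f=lorenz_evolution, g=lambda x, ph, u, ex: x.copy(),
            n=3, n_theta=3, n_phi=0, extras={"dt": 0.01},
        )
        p = [10.0, 28.0, 8 / 3]
        _, t1 = vbss.simulate(spec, p, [], np.array([1.0, 1.0, 20.0]), None, T=400)
        _, t2 = vbss.simulate(spec, p, [], np.array([1.001, 1.0, 20.0]), None, T=400)
        assert np.abs(t1.x[:, -1] - t2.x[:, -1]).max() > 5e-3

    def test_stable_linear_feedback_contracts(self):
        from vbss.models import linear_feedback_evolution

        M = np.array([[0.5, 0.2], [-0.1, 0.6]])
        spec = ModelSpec(
            f=linear_feedback_evolution, g=lambda x, ph, u, ex: x.copy(),
            n=2, n_theta=0, n_phi=0, extras={"M": M},
        )
        _, traj = vbss.simulate(spec, [], [], np.array([3.0, -2.0]), None, T=20)
        norms = np.linalg.norm(traj.x, axis=0)
        assert np.all(np.diff(norms) < 0)

    def test_registry_mappings_are_pure(self):
        from vbss.models import REGISTRY

        x = np.array([0.2, -0.4, 0.1])
        for name in ("lorenz", "double_well", "vanderpol"):
            fn = REGISTRY[name]
            xx = x[:3] if name == "lorenz" else x[:2] if name == "vanderpol" else x[:1]
            p = [10.0, 28.0, 8 / 3] if name == "lorenz" else [1.0]
            a = fn(xx.copy(), p, np.zeros(0), {"dt": 0.01})
            b = fn(xx.copy(), p, np.zeros(0), {"dt": 0.01})
            assert np.array_equal(a, b)


class TestSigmoidClassifier:
    def test_null_mapping_gives_chance(self):
        for u in np.random.default_rng(0).standard_normal((5, 2)):
            p = sigmoid_classifier_observation(np.zeros(0), [0.0, 0.0, 0.0], u, {})
            assert p[0] == pytest.approx(0.5)

    def test_separable_data_high_training_accuracy(self):
        rng = np.random.default_rng(3)
        n = 60
        u = rng.standard_normal((2, n))
        y = (1.2 * u[0] - 0.8 * u[1] > 0).astype(float)
        spec = ModelSpec(
            f=None, g=sigmoid_classifier_observation, n=0, n_theta=0,
            n_phi=3, source="binary",
        )
        data = TimeSeriesData(y=y[None, :], u=u)
        priors = PriorBundle(
            theta=EMPTY, x0=EMPTY, phi=GaussianPrior(np.zeros(3), np.eye(3))
        )
        _, rep = vbss.invert_deterministic(data, spec, priors,
                                           InversionOptions(max_iter=32))
        assert rep.fit["balanced_accuracy"] > 0.9


class TestRfxGlm:
    def test_zero_between_subject_variance_pools(self):
        # deterministic limit: group mean posterior = precision-weighted pool
        S, reps = 8, 3
        rng = np.random.default_rng(4)
        y = 0.7 + rng.standard_normal(S * reps)
        spec, priors = rfx_glm_spec(S)
        spec.extras["reps"] = reps
        data = TimeSeriesData(y=y[:, None])
        opts = InversionOptions(
            deterministic_limit=True, fixed_noise_precision=1.0,
            max_iter=32, tol_dF=1e-9,
        )
        post, _ = vbss.invert(data, spec, priors, opts)
        v0 = priors.theta.covariance[0, 0]
        pooled = (y.sum()) / (S * reps + 1.0 / v0)
        assert abs(post.theta.mean[0] - pooled) < 1e-6

    def test_needs_at_least_two_subjects(self):
        with pytest.raises(ValueError):
            rfx_glm_spec(1)
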