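"""Core types, validation, numeric derivatives and structural transforms."""

import numpy as np
import pytest

from vbss import (
    GaussianPrior,
    GammaPrior,
    ModelSpec,
    PriorBundle,
    TimeSeriesData,
    augment_ar1,
    embed_delays,
    numeric_jacobian,
    simulate,
    validate,
    with_microtime,
)


def _lin2_spec():
    M = np.array([[0.8, 0.1], [0.0, 0.9]])
    return ModelSpec(
        f=lambda x, th, u, ex: M @ x,
        g=lambda x, ph, u, ex: x.copy(),
        n=2, n_theta=0, n_phi=0,
    )


def _lin2_priors():
    e = GaussianPrior(np.zeros(0), np.zeros((0, 0)))
    return PriorBundle(theta=e, phi=e, x0=GaussianPrior(np.zeros(2), np.eye(2)))


class TestValidate:
    def test_well_formed_passes_through(self):
        spec = _lin2_spec()
        data = TimeSeriesData(y=np.zeros((2, 5)))
        problem = validate(spec, data, _lin2_priors())
        assert problem.spec is spec
        # idempotent, side-effect free
        again = validate(spec, data, _lin2_priors())
        assert np.array_equal(again.data.y, problem.data.y)

    def test_wrong_observation_dimension_raises(self):
        spec = _lin2_spec()
        spec.g = lambda x, ph, u, ex: np.concatenate([x, [0.0]])
        data = TimeSeriesData(y=np.zeros((2, 5)))
        with pytest.raises(ValueError, match="dimension"):
            validate(spec, data, _lin2_priors())

    def test_binary_source_rejects_non_binary_values(self):
        spec = _lin2_spec()
        spec.source = "binary"
        spec.g = lambda x, ph, u, ex: np.full(1, 0.5)
        y = np.array([[0.0, 1.0, 0.5]])
        with pytest.raises(ValueError, match="binary"):
            validate(spec, TimeSeriesData(y=y), _lin2_priors())

    def test_nonfinite_mapping_output_raises(self):
        spec = _lin2_spec()
        spec.f = lambda x, th, u, ex: x * np.inf
        with pytest.raises(ValueError, match="finite"):
            validate(spec, TimeSeriesData(y=np.zeros((2, 3))), _lin2_priors())


class TestNumericJacobian:
    def test_linear_map_recovers_matrix(self):
        M = np.array([[1.0, 2.0], [-0.5, 3.0]])
        J = numeric_jacobian(lambda v: M @ v, np.array([0.3, -0.7]))
        assert np.allclose(J, M, atol=1e-8)

    def test_square_derivative(self):
        J = numeric_jacobian(lambda v: v**2, np.array([3.0]))
        assert abs(J[0, 0] - 6.0) < 1e-6

    def test_sigmoid_slope_at_zero(self):
        from vbss.models import sigmoid

        J = numeric_jacobian(lambda v: np.atleast_1d(sigmoid(v[0])), np.zeros(1))
        assert abs(J[0, 0] - 0.25) < 1e-6

    def test_nonfinite_stencil_raises(self):
        with pytest.raises(ValueError, match="stencil"):
            numeric_jacobian(lambda v: np.atleast_1d(np.log(v[0])), np.array([1e-6]))


class TestDelayEmbedding:
    def test_fibonacci_recursion(self):
        # f reads the whole history: x_{t+1} = x_t + x_{t-1}
        spec = ModelSpec(
            f=lambda X, th, u, ex: np.atleast_1d(X[0] + X[1]),
            g=lambda x, ph, u, ex: x.copy(),
            n=1, n_theta=0, n_phi=0,
            delay_matrix=np.array([1]),
            f_takes_history=True,
        )
        emb = embed_delays(spec)
        assert emb.n == 2
        data, traj = simulate(emb, [], [], np.array([1.0, 1.0]), None, T=5)
        assert np.allclose(traj.x[0], [2, 3, 5, 8, 13])

    def test_zero_delay_returns_spec_unchanged(self):
        spec = _lin2_spec()
        spec.delay_matrix = np.zeros((2, 2), dtype=int)
        assert embed_delays(spec) is spec

    def test_embedded_matches_direct_delayed_recursion(self):
        # 2-state linear feedback with cross terms delayed by 2
        M = np.array([[0.9, -0.35], [0.35, 0.9]])
        d = 2

        def f(x, th, u, ex):
            return M @ x

        spec = ModelSpec(
            f=f, g=lambda x, ph, u, ex: x.copy(), n=2, n_theta=0, n_phi=0,
            delay_matrix=np.array([[0, d], [d, 0]]),
        )
        emb = embed_delays(spec)
        assert emb.n == 2 * (d + 1)
        x0 = np.array([2.0, 0.0])
        X0 = np.tile(x0, d + 1)
        T = 30
        _, traj = simulate(emb, [], [], X0, None, T=T)
        # direct non-Markovian recursion
        hist = [x0.copy()] * (d + 1)
        direct = np.zeros((2, T))
        for t in range(T):
            cur, old = hist[-1], hist[-1 - d]
            nxt = np.array(
                [M[0, 0] * cur[0] + M[0, 1] * old[1],
                 M[1, 0] * old[0] + M[1, 1] * cur[1]]
            )
            hist.append(nxt)
            direct[:, t] = nxt
        assert np.allclose(traj.x[:2], direct, atol=1e-10)

    def test_negative_delay_rejected(self):
        with pytest.raises(ValueError, match="delays"):
            ModelSpec(
                f=lambda x, th, u, ex: x, g=lambda x, ph, u, ex: x,
                n=1, n_theta=0, n_phi=0, delay_matrix=np.array([-1]),
            )


class TestAR1Augmentation:
    def test_decay_zero_gives_white_relabelled_noise(self):
        base = ModelSpec(
            f=lambda x, th, u, ex: 0.5 * x,
            g=lambda x, ph, u, ex: x.copy(),
            n=1, n_theta=0, n_phi=0,
        )
        aug, Q = augment_ar1(base, 0.0)
        data, traj = simulate(
            aug, [], [], np.zeros(2), None, T=2048,
            state_precision=1.0, seed=0, cov_structure=Q,
        )
        x, z = traj.x[0], traj.x[1]
        # z' = 0*z + noise: z is a white sequence
        zc = z - z.mean()
        r1 = (zc[1:] @ zc[:-1]) / (zc @ zc)
        assert abs(r1) < 0.06
        # the x-transition is driven by the previous z (relabelled noise)
        innov = x[1:] - 0.5 * x[:-1] - z[:-1]
        assert np.abs(innov).max() < 0.05  # only the 1e-4-weighted own noise

    def test_geometric_decay_of_z(self):
        base = ModelSpec(
            f=lambda x, th, u, ex: 0.5 * x,
            g=lambda x, ph, u, ex: x.copy(),
            n=1, n_theta=0, n_phi=0,
        )
        aug, _ = augment_ar1(base, 0.9)
        _, traj = simulate(aug, [], [], np.array([0.0, 1.0]), None, T=10)
        assert np.allclose(traj.x[1], 0.9 ** np.arange(1, 11))

    def test_ar1_autocorrelation_structure(self):
        base = ModelSpec(
            f=lambda x, th, u, ex: 0.0 * x,
            g=lambda x, ph, u, ex: x.copy(),
            n=1, n_theta=0, n_phi=0,
        )
        aug, Q = augment_ar1(base, 0.9)
        _, traj = simulate(
            aug, [], [], np.zeros(2), None, T=2**12,
            state_precision=1.0, seed=1, cov_structure=Q,
        )
        z = traj.x[1]
        zc = z - z.mean()
        r1 = (zc[1:] @ zc[:-1]) / (zc @ zc)
        assert r1 > 0.8  # z itself strongly autocorrelated
        dz = np.diff(z) - (0.9 - 1) * z[:-1]  # innovations
        dzc = dz - dz.mean()
        assert abs((dzc[1:] @ dzc[:-1]) / (dzc @ dzc)) < 0.06

    def test_decay_outside_range_rejected(self):
        base = ModelSpec(
            f=lambda x, th, u, ex: x, g=lambda x, ph, u, ex: x,
            n=1, n_theta=0, n_phi=0,
        )
        with pytest.raises(ValueError):
            augment_ar1(base, 1.0)


class TestMicrotime:
    @staticmethod
    def _decay_spec():
        return ModelSpec(
            f=lambda x, th, u, ex: x - ex.get("step", ex.get("dt", 1.0)) * x,
            g=lambda x, ph, u, ex: x.copy(),
            n=1, n_theta=0, n_phi=0, dt=1.0, extras={"dt": 1.0},
        )

    def test_single_substep_is_identity_transform(self):
        spec = self._decay_spec()
        assert with_microtime(spec, 1) is spec

    def test_euler_error_shrinks_monotonically(self):
        errs = []
        for n_micro in (1, 2, 4, 8, 16, 32, 64):
            spec = with_microtime(self._decay_spec(), n_micro)
            _, traj = simulate(spec, [], [], np.ones(1), None, T=1)
            errs.append(abs(traj.x[0, 0] - np.exp(-1.0)))
        assert all(a > b for a, b in zip(errs, errs[1:]))

    def test_refinement_gap_decreases(self):
        # |x(n) - x(2n)| shrinks with n for a smooth field
        gaps = []
        for n_micro in (1, 2, 4, 8):
            s1 = with_microtime(self._decay_spec(), n_micro)
            s2 = with_microtime(self._decay_spec(), 2 * n_micro)
            _, t1 = simulate(s1, [], [], np.ones(1), None, T=3)
            _, t2 = simulate(s2, [], [], np.ones(1), None, T=3)
            gaps.append(np.abs(t1.x - t2.x).max())
        assert all(a > b for a, b in zip(gaps, gaps[1:]))

    def test_chaotic_sensitivity_to_discretization(self):
        from vbss.models import lorenz_evolution

        base = ModelSpec(
            f=lorenz_evolution, g=lambda x, ph, u, ex: x.copy(),
            n=3, n_theta=3, n_phi=0, dt=0.02, extras={"dt": 0.02},
        )
        p = [10.0, 28.0, 8.0 / 3.0]
        x0 = np.array([1.0, 1.0, 1.0])
        _, t1 = simulate(with_microtime(base, 10), p, [], x0, None, T=100)
        _, t0 = simulate(base, p, [], x0, None, T=100)
        assert np.abs(t1.x - t0.x).max() > 0.0

    def test_invalid_n_micro(self):
        with pytest.raises(ValueError):
            with_microtime(self._decay_spec(), 0)


class TestPriorTypes:
    def test_gamma_moments(self):
        g = GammaPrior(4.0, 2.0)
        assert g.mean == 2.0
        assert g.variance == 1.0

    def test_gamma_requires_positive(self):
        with pytest.raises(ValueError):
            GammaPrior(0.0, 1.0)

    def test_gaussian_symmetry_enforced(self):
        with pytest.raises(ValueError, match="symmetric"):
            GaussianPrior(np.zeros(2), np.array([[1.0, 0.5], [0.0, 1.0]]))

    def test_zero_variance_is_legal(self):
        g = GaussianPrior(np.array([1.5]), np.zeros((1, 1)))
        assert g.dim == 1
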