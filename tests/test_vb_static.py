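"""VB-Laplace inversion on static/deterministic models against exact oracles.

The conjugate linear-Gaussian model (fixed measurement precision) has a
closed-form posterior and evidence; these pin the parameter updates, the
free energy and the Savage-Dickey reduction to 1e-6.
"""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.stats import multivariate_normal

import vbss
from vbss import (
    GammaPrior,
    GaussianPrior,
    InversionOptions,
    ModelSpec,
    PriorBundle,
    TimeSeriesData,
)
from vbss.models import linear_observation, sigmoid, sigmoid_classifier_observation

EMPTY = GaussianPrior(np.zeros(0), np.zeros((0, 0)))


def linear_problem(seed=0, N=25, d=3, sig=4.0, prior_var=2.0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((N, d))
    beta = rng.standard_normal(d)
    y = X @ beta + rng.standard_normal(N) / np.sqrt(sig)
    spec = ModelSpec(f=None, g=linear_observation, n=0, n_theta=0, n_phi=d)
    data = TimeSeriesData(y=y[None, :], u=X.T)
    priors = PriorBundle(
        theta=EMPTY, x0=EMPTY,
        phi=GaussianPrior(np.zeros(d), np.eye(d) * prior_var),
    )
    return X, y, sig, spec, data, priors


def exact_log_evidence(X, y, S0, mu0, sig):
    C = X @ S0 @ X.T + np.eye(len(y)) / sig
    return multivariate_normal.logpdf(y, X @ mu0, C)


class TestConjugateExactness:
    def test_posterior_matches_closed_form(self):
        X, y, sig, spec, data, priors = linear_problem()
        opts = InversionOptions(fixed_noise_precision=sig, tol_dF=1e-10, max_iter=64)
        post, rep = vbss.invert_deterministic(data, spec, priors, opts)
        S0 = priors.phi.covariance
        Sp = np.linalg.inv(np.linalg.inv(S0) + sig * X.T @ X)
        mp = Sp @ (sig * X.T @ y)
        assert np.abs(post.phi.mean - mp).max() < 1e-6
        assert np.abs(post.phi.covariance - Sp).max() < 1e-6

    def test_free_energy_equals_log_evidence(self):
        X, y, sig, spec, data, priors = linear_problem(seed=3)
        opts = InversionOptions(fixed_noise_precision=sig, tol_dF=1e-10, max_iter=64)
        _, rep = vbss.invert_deterministic(data, spec, priors, opts)
        exact = exact_log_evidence(X, y, priors.phi.covariance, priors.phi.mean, sig)
        assert abs(rep.free_energy - exact) < 1e-6

    def test_invert_delegates_for_static_models(self):
        # n = 0: invert and invert_deterministic coincide
        X, y, sig, spec, data, priors = linear_problem(seed=5)
        opts = InversionOptions(fixed_noise_precision=sig, tol_dF=1e-10, max_iter=64)
        p1, r1 = vbss.invert(data, spec, priors, opts)
        p2, r2 = vbss.invert_deterministic(data, spec, priors, opts)
        assert r1.free_energy == r2.free_energy
        assert np.array_equal(p1.phi.mean, p2.phi.mean)

    def test_monotone_trace(self):
        X, y, sig, spec, data, priors = linear_problem(seed=7)
        _, rep = vbss.invert_deterministic(data, spec, priors)
        assert np.all(np.diff(rep.free_energy_trace) >= -1e-8)


class TestFreeEnergyEdgeCases:
    def test_all_excluded_data_gives_zero_at_prior(self):
        X, y, sig, spec, data, priors = linear_problem(N=10)
        data = TimeSeriesData(
            y=data.y, u=data.u, exclusion_mask=np.ones_like(data.y, dtype=bool)
        )
        problem = vbss.validate(spec, data, priors)
        from vbss.inversion.common import GammaStats
        from vbss.inversion import Posterior

        q = Posterior(
            theta=priors.theta, phi=priors.phi, x0=priors.x0,
            noise_precision=GammaStats(1.0, 1.0, fixed_value=sig),
        )
        assert abs(vbss.free_energy(problem, q)) < 1e-8

    def test_excluded_sample_equals_deleted_sample(self):
        X, y, sig, spec, data, priors = linear_problem(seed=11, N=20)
        mask = np.zeros_like(data.y, dtype=bool)
        mask[0, 7] = True
        masked = TimeSeriesData(y=data.y, u=data.u, exclusion_mask=mask)
        keep = np.ones(20, dtype=bool)
        keep[7] = False
        deleted = TimeSeriesData(y=data.y[:, keep], u=data.u[:, keep])
        opts = InversionOptions(fixed_noise_precision=sig, tol_dF=1e-10, max_iter=64)
        _, r1 = vbss.invert_deterministic(masked, spec, priors, opts)
        _, r2 = vbss.invert_deterministic(deleted, spec, priors, opts)
        assert abs(r1.free_energy - r2.free_energy) < 1e-8


class TestParameterUpdates:
    def test_quadratic_energy_single_newton_step(self):
        # linear model: the first GN step lands on the exact mode
        X, y, sig, spec, data, priors = linear_problem(seed=2)
        problem = vbss.validate(spec, data, priors)
        from vbss.inversion.common import GammaStats
        from vbss.inversion import Posterior

        q = Posterior(
            theta=priors.theta, phi=priors.phi, x0=priors.x0,
            noise_precision=GammaStats(1.0, 1.0, fixed_value=sig),
        )
        opts = InversionOptions(gn_max_iter=1)
        out = vbss.update_params(problem, "phi", q, opts)
        S0 = priors.phi.covariance
        Sp = np.linalg.inv(np.linalg.inv(S0) + sig * X.T @ X)
        mp = Sp @ (sig * X.T @ y)
        assert np.abs(out.phi.mean - mp).max() < 1e-6

    def test_zero_prior_variance_fixes_coordinate(self):
        X, y, sig, spec, data, priors = linear_problem(seed=4)
        cov = priors.phi.covariance.copy()
        cov[1, :] = 0.0
        cov[:, 1] = 0.0
        mean = np.array([0.0, 0.77, 0.0])
        priors = PriorBundle(theta=EMPTY, x0=EMPTY, phi=GaussianPrior(mean, cov))
        opts = InversionOptions(fixed_noise_precision=sig, max_iter=32)
        post, _ = vbss.invert_deterministic(data, spec, priors, opts)
        assert post.phi.mean[1] == 0.77
        assert post.phi.covariance[1, 1] == 0.0

    def test_logistic_mode_matches_generic_optimizer(self):
        # separable data: the Gaussian prior keeps the mode finite
        rng = np.random.default_rng(6)
        n, d = 40, 2
        u = rng.standard_normal((d, n))
        y = (u[0] + u[1] > 0).astype(float)
        spec = ModelSpec(
            f=None, g=sigmoid_classifier_observation, n=0, n_theta=0,
            n_phi=d + 1, source="binary",
        )
        data = TimeSeriesData(y=y[None, :], u=u)
        priors = PriorBundle(
            theta=EMPTY, x0=EMPTY,
            phi=GaussianPrior(np.zeros(d + 1), np.eye(d + 1)),
        )
        post, _ = vbss.invert_deterministic(
            data, spec, priors, InversionOptions(tol_dF=1e-8, max_iter=64)
        )

        def neg_penalized(phi):
            eta = phi[:-1] @ u + phi[-1]
            p = 1 / (1 + np.exp(-eta))
            p = np.clip(p, 1e-12, 1 - 1e-12)
            return -(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))
                     - 0.5 * phi @ phi)

        res = minimize(neg_penalized, np.zeros(d + 1), method="BFGS")
        assert np.abs(post.phi.mean - res.x).max() < 1e-4


class TestPrecisionUpdates:
    def test_conjugate_normal_gamma_closed_form(self):
        # phi fixed at truth: shape/rate updates are textbook conjugate
        X, y, sig, spec, data, _ = linear_problem(seed=8)
        beta_hat = np.linalg.lstsq(X, y, rcond=None)[0]
        priors = PriorBundle(
            theta=EMPTY, x0=EMPTY,
            phi=GaussianPrior(beta_hat, np.zeros((3, 3))),
            noise_precision=GammaPrior(2.0, 0.5),
        )
        problem = vbss.validate(spec, data, priors)
        from vbss.inversion.common import GammaStats
        from vbss.inversion import Posterior

        q = Posterior(
            theta=priors.theta, phi=priors.phi, x0=priors.x0,
            noise_precision=GammaStats(2.0, 0.5),
        )
        out = vbss.update_precisions(problem, q)
        rss = float(np.sum((y - X @ beta_hat) ** 2))
        assert out.noise_precision.a == pytest.approx(2.0 + len(y) / 2, abs=1e-12)
        assert out.noise_precision.b == pytest.approx(0.5 + rss / 2, abs=1e-9)

    def test_deterministic_limit_freezes_state_precision(self):
        spec = ModelSpec(
            f=lambda x, th, u, ex: 0.9 * x,
            g=lambda x, ph, u, ex: x.copy(),
            n=1, n_theta=0, n_phi=0,
        )
        data, _ = vbss.simulate(
            spec, [], [], np.ones(1), None, T=32,
            state_precision=10.0, noise_precision=10.0, seed=0,
        )
        priors = PriorBundle(
            theta=EMPTY, phi=EMPTY, x0=GaussianPrior([1.0], np.zeros((1, 1)))
        )
        opts = InversionOptions(deterministic_limit=True)
        post, _ = vbss.invert(data, spec, priors, opts)
        assert post.state_precision.a == priors.state_precision.a
        assert post.state_precision.b == priors.state_precision.b


class TestSavageDickey:
    def test_identity_reduction_is_zero(self):
        g = GaussianPrior(np.zeros(2), np.eye(2))
        post = GaussianPrior(np.array([0.3, -0.2]), np.eye(2) * 0.1)
        assert vbss.savage_dickey(post, g, g) == pytest.approx(0.0, abs=1e-12)

    def test_matches_analytic_nested_evidence_difference(self):
        X, y, sig, spec, data, priors = linear_problem(seed=9, N=20)
        opts = InversionOptions(fixed_noise_precision=sig, tol_dF=1e-10, max_iter=64)
        post, _ = vbss.invert_deterministic(data, spec, priors, opts)
        S0r = priors.phi.covariance.copy()
        S0r[1, :] = 0.0
        S0r[:, 1] = 0.0
        reduced = GaussianPrior(priors.phi.mean, S0r)
        lbf = vbss.savage_dickey(post.phi, priors.phi, reduced)
        keep = [0, 2]
        exact = (
            exact_log_evidence(X[:, keep], y,
                               priors.phi.covariance[np.ix_(keep, keep)],
                               priors.phi.mean[keep], sig)
            - exact_log_evidence(X, y, priors.phi.covariance,
                                 priors.phi.mean, sig)
        )
        assert abs(lbf - exact) < 1e-6

    def test_posterior_far_from_reduction_point_favours_full(self):
        post = GaussianPrior(np.array([5.0]), np.eye(1) * 0.01)
        full = GaussianPrior(np.zeros(1), np.eye(1))
        red = GaussianPrior(np.zeros(1), np.zeros((1, 1)))
        assert vbss.savage_dickey(post, full, red) < 0

    def test_non_nested_reduction_rejected(self):
        full = GaussianPrior(np.zeros(2), np.diag([1.0, 0.0]))
        red = GaussianPrior(np.zeros(2), np.diag([1.0, 1.0]))
        post = GaussianPrior(np.zeros(2), np.eye(2) * 0.1)
        with pytest.raises(ValueError, match="nested"):
            vbss.savage_dickey(post, full, red)
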