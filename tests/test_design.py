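"""Design scoring: predictive densities, Chernoff risk, A-optimality."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

import vbss
from vbss import (
    GammaPrior,
    GaussianPrior,
    ModelSpec,
    PriorBundle,
    PredictiveDensity,
    a_optimality,
    block_design,
    chernoff_risk,
    online_design_step,
    prior_predictive,
)
from vbss.models import linear_observation, sigmoid

EMPTY = GaussianPrior(np.zeros(0), np.zeros((0, 0)))


def linear_spec(d):
    return ModelSpec(f=None, g=linear_observation, n=0, n_theta=0, n_phi=d)


def linear_priors(d, var=1.5, noise=(2.0, 0.5)):
    return PriorBundle(
        theta=EMPTY, x0=EMPTY,
        phi=GaussianPrior(np.zeros(d), np.eye(d) * var),
        noise_precision=GammaPrior(*noise),
    )


class TestPriorPredictive:
    def test_linear_model_exact_gaussian(self):
        d, N = 3, 7
        rng = np.random.default_rng(0)
        X = rng.standard_normal((N, d))
        priors = linear_priors(d)
        pd = prior_predictive(linear_spec(d), priors, X.T)
        noise_var = priors.noise_precision.b / priors.noise_precision.a
        expected = X @ priors.phi.covariance @ X.T + noise_var * np.eye(N)
        assert np.allclose(pd.mean, X @ priors.phi.mean, atol=1e-8)
        assert np.allclose(pd.covariance, expected, atol=1e-6)

    def test_zero_prior_variance_leaves_noise_only(self):
        d, N = 2, 5
        X = np.random.default_rng(1).standard_normal((N, d))
        priors = linear_priors(d, var=0.0)
        pd = prior_predictive(linear_spec(d), priors, X.T)
        noise_var = priors.noise_precision.b / priors.noise_precision.a
        assert np.allclose(pd.covariance, noise_var * np.eye(N), atol=1e-10)

    def test_sigmoid_model_within_monte_carlo_band(self):
        # small prior variance: linearization bias below 3 MC standard errors
        rng = np.random.default_rng(2)
        u = np.array([[0.5, -1.0, 1.5]])
        spec = ModelSpec(
            f=None,
            g=lambda x, ph, u_, ex: np.atleast_1d(sigmoid(ph[0] * u_[0])),
            n=0, n_theta=0, n_phi=1,
        )
        priors = PriorBundle(
            theta=EMPTY, x0=EMPTY,
            phi=GaussianPrior(np.array([1.0]), np.eye(1) * 0.01),
        )
        pd = prior_predictive(spec, priors, u)
        n_draws = 2**14
        phis = 1.0 + 0.1 * rng.standard_normal(n_draws)
        sims = sigmoid(np.outer(phis, u[0]))
        mc_mean = sims.mean(axis=0)
        mc_se = sims.std(axis=0) / np.sqrt(n_draws)
        assert np.all(np.abs(pd.mean - mc_mean) < 3 * mc_se + 1e-3)


class TestChernoffRisk:
    def test_identical_predictions_maximal_risk(self):
        p = PredictiveDensity(np.zeros(3), np.eye(3))
        q = PredictiveDensity(np.zeros(3), np.eye(3))
        assert chernoff_risk(p, q) == pytest.approx(0.5)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.floats(0.01, 10), st.floats(0.01, 10))
    def test_symmetric_and_bounded(self, a, b):
        p = PredictiveDensity(np.array([a]), np.eye(1))
        q = PredictiveDensity(np.array([-b]), np.eye(1) * 1.3)
        r1, r2 = chernoff_risk(p, q), chernoff_risk(q, p)
        assert r1 == pytest.approx(r2, abs=1e-14)
        assert 0.0 <= r1 <= 0.5

    def test_strictly_decreasing_in_separation(self):
        risks = [
            chernoff_risk(
                PredictiveDensity(np.array([dg]), np.eye(1)),
                PredictiveDensity(np.array([0.0]), np.eye(1)),
            )
            for dg in (0.0, 0.5, 1.0, 2.0, 4.0)
        ]
        assert all(a > b for a, b in zip(risks, risks[1:]))

    def test_rank_agreement_with_exact_overlap_error(self):
        # exact Bayes selection error = integral of the minimum density / 2
        def exact_error(dg, sd=1.0):
            f = lambda y: 0.5 * min(
                np.exp(-0.5 * ((y - dg / 2) / sd) ** 2),
                np.exp(-0.5 * ((y + dg / 2) / sd) ** 2),
            ) / (sd * np.sqrt(2 * np.pi))
            return quad(f, -12, 12)[0]

        dgs = [0.5, 1.0, 2.0, 4.0]
        risks, errors = [], []
        for dg in dgs:
            risks.append(chernoff_risk(
                PredictiveDensity(np.array([dg / 2]), np.eye(1)),
                PredictiveDensity(np.array([-dg / 2]), np.eye(1)),
            ))
            errors.append(exact_error(dg))
        assert np.argsort(risks).tolist() == np.argsort(errors).tolist()
        # both decrease with separation
        assert all(a > b for a, b in zip(errors, errors[1:]))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            chernoff_risk(
                PredictiveDensity(np.zeros(2), np.eye(2)),
                PredictiveDensity(np.zeros(3), np.eye(3)),
            )


class TestAOptimality:
    def test_matches_closed_form_posterior_trace(self):
        d, N = 3, 12
        X = np.random.default_rng(3).standard_normal((N, d))
        priors = linear_priors(d, var=2.0, noise=(4.0, 1.0))
        score = a_optimality(linear_spec(d), priors, X.T)
        noise_var = priors.noise_precision.b / priors.noise_precision.a
        closed = np.trace(np.linalg.inv(
            np.linalg.inv(priors.phi.covariance) + X.T @ X / noise_var
        ))
        assert abs(score - closed) < 1e-8

    def test_duplicating_design_never_hurts(self):
        d = 2
        X = np.random.default_rng(4).standard_normal((6, d))
        priors = linear_priors(d)
        s1 = a_optimality(linear_spec(d), priors, X.T)
        s2 = a_optimality(linear_spec(d), priors, np.concatenate([X, X]).T)
        assert s2 <= s1 + 1e-12

    def test_monotone_in_independent_measurements(self):
        d = 2
        rng = np.random.default_rng(5)
        X = rng.standard_normal((20, d))
        priors = linear_priors(d)
        scores = [
            a_optimality(linear_spec(d), priors, X[:n].T) for n in (4, 8, 16, 20)
        ]
        assert all(a >= b for a, b in zip(scores, scores[1:]))

    def test_uninformative_design_returns_prior_trace(self):
        d = 2
        priors = linear_priors(d, var=1.5)
        spec = ModelSpec(
            f=None, g=lambda x, ph, u, ex: np.atleast_1d(1.0),
            n=0, n_theta=0, n_phi=d,
        )
        score = a_optimality(spec, priors, np.zeros((1, 4)))
        assert abs(score - np.trace(priors.phi.covariance)) < 1e-6


class TestOnlineDesignStep:
    def test_single_candidate_returned(self):
        d = 1
        cand = np.array([[1.0, 1.0]])
        models = [
            (linear_spec(d), linear_priors(d)),
            (linear_spec(d), PriorBundle(
                theta=EMPTY, x0=EMPTY,
                phi=GaussianPrior(np.array([1.0]), np.zeros((1, 1))),
            )),
        ]
        out = online_design_step([cand], models)
        assert out.index == 0

    def test_more_separating_candidate_wins(self):
        d = 1
        m1 = (linear_spec(d), PriorBundle(
            theta=EMPTY, x0=EMPTY,
            phi=GaussianPrior(np.array([1.0]), np.zeros((1, 1)))))
        m2 = (linear_spec(d), PriorBundle(
            theta=EMPTY, x0=EMPTY,
            phi=GaussianPrior(np.array([-1.0]), np.zeros((1, 1)))))
        weak = np.array([[0.1, 0.1]])
        strong = np.array([[2.0, 2.0]])
        out = online_design_step([weak, strong], [m1, m2])
        assert out.index == 1

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            online_design_step([], [])


class TestBlockDesign:
    def test_alternating_attention_correlation(self):
        # photic always on during stimulation, attention on alternate blocks
        u = block_design(10, attention_blocks=range(0, 10, 2))
        r = np.corrcoef(u[0], u[1])[0, 1]
        assert round(r, 1) == 0.6

    def test_shapes_and_boxcar(self):
        u = block_design(3, [1], block_on=4, block_off=4)
        assert u.shape == (2, 24)
        assert u[0, :4].all() and not u[0, 4:8].any()
        assert u[1, 8:12].all() and u[1].sum() == 4
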