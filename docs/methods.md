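# Methods

## Generative model

`vbss` inverts discrete-time stochastic nonlinear state-space models

    x_t = f(x_{t-1}, θ, u_t) + η_t,   η_t ~ N(0, Q/α)
    y_t = g(x_t,     φ, u_t) + ε_t,   ε_t ~ N(0, I/σ)     (continuous)
    y_t ~ Bernoulli(g(x_t, φ, u_t))                        (binary)

for t = 1..T, with x_1 = f(x0, θ, u_1). Input column t feeds both the
transition into t and the observation at t; this single indexing convention
is used by every model in the library. Gaussian priors are placed on θ, φ
and x0 (a zero prior variance fixes a coordinate to its prior mean), and
Gamma(a, b) priors on the two precisions (mean a/b, variance a/b²). An
optional structure matrix Q reweights the state noise across state
coordinates — this is how near-deterministic blocks (e.g. the value states
of the dynamic-learning-rate model, or the x-block of the AR(1)
augmentation) are expressed while one scalar precision α sets the overall
level. Excluded samples (mask entries, missing CSV cells) contribute
nothing to the likelihood: inverting with a masked sample is identical to
inverting with that sample deleted.

## Variational inversion

The posterior over (x, θ, φ, x0, α, σ) is approximated by a mean-field
product of Gaussian blocks (Gamma for the precisions), and inference
maximizes the free energy

    F = E_q[log p(y, x, θ, φ, x0, α, σ)] + H[q] ≤ log p(y | m),

which equals the exact log evidence when q matches the true posterior —
in particular on linear-Gaussian models with fixed measurement precision,
where F is verified against the closed-form evidence to better than 1e-6.
Expectations of nonlinear terms use the delta method (second-order/Fisher
trace corrections around the block means), i.e. the Laplace variant of
variational Bayes.

Coordinate updates per iteration, in order:

1. **States** — a lagged Kalman-style forward pass. At time t the pass
   carries a joint Gaussian over the window x_{t-k-1..t} (k = `lag_k`),
   predicts with the local linearization of f (analytic Jacobians are used
   when a model supplies them, central differences otherwise), assimilates
   y_t (binary observations enter through a moment-matched Gaussian with
   variance g(1-g)), and freezes the statistics of x_{t-k}. k = 0
   reproduces the filtering recursion exactly; k ≥ T reproduces
   fixed-interval smoothing (verified against an independent RTS smoother
   at 1e-6); intermediate k trades computation (cost grows with the cube
   of the window) against the temporal range over which later observations
   inform earlier states — essential for convolution-like dynamics and
   delayed noise. Alongside the per-time marginals the pass records the
   joint mean/covariance of each consecutive pair (x_{t-1}, x_t) under a
   single conditioning set; the free-energy transition and entropy terms
   are computed from these pairs. (Mixing the lag-k marginal of x_{t-1}
   with the lag-(k+1) cross-covariance is catastrophic when Q is stiff —
   the inconsistency is amplified by the largest eigenvalue of Q⁻¹.)
2. **Observation parameters φ**, then **evolution parameters (θ, x0)** —
   regularized Gauss–Newton ascent of the block's variational energy
   (Levenberg jitter 1e-8·trace/dim on the curvature, step halving up to
   32 times, a step accepted only if the energy improves; a stalled block
   keeps its previous statistics). The block covariance is the inverse
   curvature at the mode, computed without the stepping jitter so that
   downstream density ratios (Savage–Dickey) retain full accuracy.
3. **Precisions** — conjugate-style Gamma updates: posterior shape = prior
   shape + (number of residual terms)/2, posterior rate = prior rate +
   (expected weighted sum of squared residuals)/2, expectations under the
   current Gaussian blocks. Either precision can be clamped
   (`fixed_noise_precision`, `fixed_state_precision`); the deterministic
   limit clamps α implicitly.

Each block update is accepted only if the recomputed F does not decrease,
so the recorded free-energy trace is non-decreasing by construction; when
no single block improves F (states and precisions sometimes have to move
together, e.g. under stiff Q), up to eight chained full sweeps are tried
and accepted as a whole if they beat the gated value. Iteration stops when
|ΔF| < `tol_dF` (default 2e-2) or after `max_iter` (default 32) cycles.

Stochastic inversions are initialized from the deterministic variant of
the model: the static inversion below provides (θ, φ, x0, σ), the
deterministic trajectory seeds the state means, and one unconditional
state pass completes the initialization before the monotone regime starts.

**Deterministic / static models.** At the infinite-α limit the states are
the deterministic image of (θ, x0, u) and the model is treated as a static
nonlinear regression: the same Gauss–Newton machinery fits (θ, x0) through
the composed trajectory and φ through the observation, with the
delta-method trace corrections propagated through the composition. Static
models (n = 0) and the two-level mixed-effects construction (group mean
broadcast into per-subject effect states, between-subject precision = α)
are special cases. A post-hoc joint Laplace covariance over (θ, x0, φ) is
computed at convergence for identifiability diagnostics (mean-field blocks
alone carry no between-block correlation).

**Binary data.** The Bernoulli likelihood uses g clipped to
[1e-8, 1-1e-8]; Gauss–Newton uses the Fisher (IRLS) curvature, and the
free energy adds the Fisher trace correction for parameter/state
uncertainty. No measurement precision exists for binary sources.

## Model comparison

F is used as the log model evidence throughout. Subject-level posterior
model probabilities are softmax(F + log prior); family posteriors sum
member probabilities under a uniform model prior. Savage–Dickey /
Gaussian-model-reduction gives the log Bayes factor of a nested prior
reduction directly from the full model's prior and posterior (exact for
linear-Gaussian models; point reductions use the marginal density ratio,
finite-variance reductions the general Gaussian reduction formula).
Group-level random-effects selection iterates per-subject attributions
u_sk ∝ exp(F_sk + ψ(α_k) − ψ(Σα)) against Dirichlet counts
α_k = α0_k + Σ_s u_sk until the counts move by less than 1e-6 (prior
counts default to 1). Exceedance probabilities use the exact Beta integral
for two models and seeded Dirichlet Monte-Carlo (2^16 draws) otherwise;
the fixed-effects log group Bayes factor (column sums) is reported
alongside.

## Design optimization

The predictive density of a design u under a model is the delta-method
Gaussian: mean = composed prediction at the prior (or current posterior)
means, covariance = J Σ Jᵀ plus the expected noise covariance, where the
expected noise variance is the prior-mean precision's inverse b/a. For
parameter estimation the score is A-optimality, trace((Σ0⁻¹ + JᵀJ/σ²)⁻¹)
in the linear case (matched to the closed form at 1e-8). For model
selection between two a-priori equiprobable models with similar predictive
variances the Laplace–Chernoff risk is

    risk = 1/2 exp( -(1/8) Δg' Σ̄⁻¹ Δg ),

with Δg the difference of the predictive means and Σ̄ the average
predictive covariance — the Chernoff/Bhattacharyya bound on the Bayes
selection error, maximal (1/2) for indistinguishable predictions, strictly
decreasing in ‖Δg‖, and rank-consistent with the exact overlap error
(verified by quadrature and Monte-Carlo, Kendall τ = 1 across the test
designs). The online loop scores each candidate next block by the risk of
the model comparison with the current posteriors standing as priors
(re-linearizing around the posterior means each block, and evaluating the
candidate block's samples within the concatenated design so convolution
tails carry over); ties break in candidate order.

## Diagnostics

Residual autocorrelation is the normalized sample ACF with the
±1.96/√T white-noise band. For state-noise misspecification the package
also exposes one-step filter innovations y_t − g(f(x_{t-1|t-1})): smoothed
residuals y − g(E[x|y]) are serially correlated even under the true model
whenever measurement noise is small relative to the state noise (verified
with an exact smoother at the true precisions), whereas innovations are
approximately white under a correct model and inherit unmodelled drive
correlation under a misspecified one. Fit summaries report percentage of
variance explained (continuous) or balanced accuracy (binary) plus the
log-likelihood at the posterior means. First-order Volterra kernels are
ordinary least squares of a series onto lagged inputs (lags 0..depth-1,
default depth 16, intercept included, homoscedastic standard errors).

## Synthetic-data generators

Every experiment regenerates its data by seeded simulation
(`vbss.fixtures`); there are no external datasets. Protocol constants
follow the study descriptions where stated: go/no-go feedback frequencies
2/5 positive, 2/5 negative, 1/5 neutral, value data at SNR = 1 dB
(variance-ratio decibels, the standard reading), two groups of 32 subjects
with the reduced group expressing half of the four GLM factors at
SNR = 0 dB, 16 s on / 16 s off stimulation blocks with attention gating
the V1→V5 modulation, bandit contingency reversals every fifty trials, and
a learning-rate state whose noise precision is set one hundred times
smaller than the action values'. Where a protocol constant is not stated
the generators fix one plausible value (documented in the builder
docstrings): e.g. learning rate 0.5 with gain weight 2 vs loss weight 1
for the asymmetric-utility agent; Lorenz (10, 28, 8/3) at dt = 0.02 with
two Euler sub-steps; AR(1) decay 0.8; 400 bandit trials with reward
probability 0.9 and a softmax temperature low enough that choices do not
saturate (saturated choices carry almost no information about the learning
rate). Problem sizes (tens to a few hundred samples, 16–100 Monte-Carlo
replicates) are desk-scale choices that keep each experiment in seconds to
a couple of minutes.

What the generators deliberately do not emulate: real fMRI physiology (the
hemodynamic step is a linear double-gamma convolution, not a nonlinear
Balloon-type model), the volatility-tracking Bayesian agent behind the
bandit demo (replaced by a scripted instability-driven learning-rate
process — the diagnostic chain being tested is identical), multinomial
observations, and structured measurement covariances. Passing tests
therefore certify the inference machinery and the qualitative phenomena,
not biophysical realism.

## Numerical choices and limitations

- Numeric Jacobians: central differences with step 1e-4·max(1, |coord|);
  models may supply analytic Jacobians (`df_dx`, `df_dp`, `dg_dx`,
  `dg_dp`), which the state pass uses directly.
- Delay embedding stores history newest-first; `f_takes_history` lets an
  evolution read the whole embedded history (two-term recursions); an
  integer delay vector/matrix adapts ordinary evolutions per coordinate.
- The AR(1) augmentation down-weights the x-block state noise by 1e-4
  relative to the noise carrier, and such stiff structure matrices need a
  lag of ~4 for the pass statistics to be consistent enough that the
  precision updates calibrate.
- Trajectory-level observations (convolution models) are supported by the
  deterministic engine only; the lagged pass requires pointwise g. Long
  convolutions can alternatively be expressed as FIR delay embeddings.
- Mean-field precision estimates are accurately calibrated when state and
  measurement noise are of comparable size (measurement precision within
  1.5% at T = 4096 in the balanced regime) but acquire a deterministic
  bias of tens of percent when one source dominates: the self-consistency
  between the state pass and the Gamma update has high loop gain there
  (the update map drifts away from the truth even when started at it).
  Evidence comparisons between models of the same data are much less
  affected than the absolute precision values.
- Free-energy monotonicity is enforced by acceptance, so a "converged"
  flag can also mean the coordinate scheme found no improving move; the
  chained-sweep fallback escapes the common stalls, but multi-modal state
  posteriors (chaotic systems) retain local optima — the Lorenz inversion
  is compared on F values, not on trajectory recovery.
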