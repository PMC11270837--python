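# Methods

## The rate model

A rare barrier-crossing is modelled as a Poisson escape with survival
function S(t) = exp(−k₀t).  When a time-dependent repulsive bias V(ξ, t) is
added along a collective variable (CV) to accelerate escapes, the rate
becomes time dependent, k(t) = k₀ f(t), and

    S(t) = exp(−k₀ Γ(t)),    Γ(t) = ∫₀ᵗ f(t′) dt′.

For an ensemble of N trajectories of which M transitioned at times tᵢ and
N−M were right-censored at Tᵢ, the log-likelihood is

    log L = Σ_events [log k₀ + log f(tᵢ) − k₀ Γ(tᵢ)] − Σ_censored k₀ Γ(Tᵢ),

which for any fixed scaling function concentrates to the closed form
k₀*(f) = M / Σᵢ Γ(τᵢ).  The three estimators differ only in f:

| method | scaling function f(t) | free parameters |
|---|---|---|
| iMetaD | e^{βVᵢ(t)} per trajectory (hyperdynamics ansatz) | k₀ |
| KTR    | exp(γβ⟨max_{t′≤t} Vᵢ(t′)⟩) | k₀, γ |
| EATR   | ⟨e^{γβVᵢ(t)}⟩ | k₀, γ |

⟨·⟩ averages over trajectories and γ ∈ [0, 1] is the CV biasing
efficiency: the fraction of the applied bias that actually promotes the
transition.  γ = 1 means an ideal CV; for EATR at γ = 1 with every
trajectory transitioned, the idempotence of averages reduces
k₀*(γ) = N / Σᵢ ∫₀^{tᵢ} e^{γβVᵢ} dt to exactly the iMetaD rescaled-time
estimator (the two code paths are literally the same function here, so the
identity holds bitwise).  The γ-dependence of the concentrated likelihood
always uses the ensemble-averaged EATR scaling; without that average the
likelihood carries no information about γ.

γ is found by maximizing the concentrated likelihood on a deterministic
grid (default 41 points on [0, 1]) followed by bounded scalar refinement.
If the scan varies by less than the optimizer tolerance (zero bias, or an
effectively time-independent bias such as converged OPES flooding), the
estimate carries a `degenerate` flag; γ is then not identifiable from the
likelihood and the slope method below is the appropriate tool.

## CDF fitting

As an alternative to likelihood maximization, 1 − S(t) is fitted to the
empirical CDF of observed event times by least squares, with residuals at
the observed event times only (dense parts of the distribution weight
themselves).  Initial guesses come from the likelihood estimate; k₀ is
fitted as log₁₀k₀ and γ within bounds.  We use the trust-region-reflective
least-squares solver rather than plain Levenberg–Marquardt because the
latter cannot enforce the γ ∈ [0, 1] bounds; for interior optima the two
coincide.

The model CDFs are:

* unbiased: 1 − e^{−k₀t};
* iMetaD: 1 − ⟨e^{−k₀ αᵢ t}⟩ with αᵢ the trajectory's *overall*
  acceleration factor (1/tᵢ)∫₀^{tᵢ} e^{βVᵢ} dt.  Each trajectory
  contributes a single exponential component with its own constant
  acceleration;
* KTR/EATR: exp(−k₀ Γ(t; γ)) with the ensemble-averaged scaling.

### Ensemble averages past a trajectory's end

The ensemble averages ⟨max Vᵢ(t)⟩ and ⟨e^{γβVᵢ(t)}⟩ need Vᵢ(t) at times
after trajectory i has already transitioned, where nothing was simulated.
Two conventions are implemented:

* **risk-set** (default): at time t the average runs over the trajectories
  still unterminated at t (the survival-analysis risk set); once the risk
  set is empty the scaling is frozen at its last value.
* **freeze**: terminated trajectories stay in the average with their bias
  frozen at the final recorded value.

The freeze convention systematically *underestimates* the late-time
scaling whenever escapes are spread over the bias-growth period, because a
frozen trajectory's bias no longer grows while the survivors' does; on the
1D benchmark at slow deposition this inflates CDF-fitted rates by about
0.15–0.2 in log₁₀.  The risk-set average does not have this defect and is
therefore the default; the freeze variant is kept as an option
(`FitConfig(tail="freeze")`) for comparison.  Likelihood fits with
M = N are unaffected by the convention for iMetaD/EATR's per-trajectory
denominators, which integrate each trajectory only to its own event time.

## The OPES-slope fit

A converged flooding bias is essentially constant in time, so f(t) is a
constant and the likelihood cannot separate k₀ from γ (the degenerate
case above).  Running several ensembles at different barrier parameters ΔE
gives one observed rate each, and under the model
k_obs = k₀ e^{γβ·v̄} a weighted linear regression of log k_obs on β v̄
(weights = events per ensemble) returns γ as the slope and k₀ from the
intercept.  The scalar bias measure v̄ is the ensemble average of either
the per-trajectory maximum bias (`plateau_max`, default) or the
time-averaged bias (`time_average`); both are exposed because either is a
defensible plateau summary.

## Uncertainty and goodness of fit

Bootstrap errors resample whole trajectories (record + bias trace jointly)
with replacement to the original N, re-run the estimator, and report the
standard deviation of log₁₀k₀ and of γ over replicates (default 100).
Resamples on which the estimator fails are redrawn up to a retry cap.

Goodness of fit uses Kolmogorov–Smirnov tests with the conventional pass
threshold p > 0.05: a two-sample test against a large (default 10⁵)
inverse-CDF draw from the fitted model for the unbiased and iMetaD
estimators, and a one-sample test against the theoretical CDF for KTR and
EATR.  Censored trajectories are excluded from KS samples, which require
fully observed event times.

## The 1D benchmark simulator

The matched-harmonic potential joins two harmonic branches of equal
curvature κ = 4ΔU/(x₁−x₀)² at the midpoint x_b = (x₀+x₁)/2, giving
U(x₀) = 0, U(x₁) = ΔU and continuity of U and U′.  Default parameters are
x₀ = −3, x₁ = 3, ΔU = 8 k_BT, overdamped dynamics with D = 0.02 (friction
ζ = 50 τ⁻¹) and an Euler–Maruyama step of dt = 0.01 τ, all in reduced
units.  The Smoluchowski-limit Kramers rate
k = Dβκ/(2π)·e^{−βΔU} = 9.49 × 10⁻⁷ τ⁻¹ for these parameters, and the
mean-first-passage double integral evaluates to log₁₀k = −6.02.

**Absorbing boundary.**  First passage is recorded at x₁ + 4σ_b
(σ_b = √(k_BT/κ)), on the product side where the outer integrand of the
double integral has converged.  Absorbing exactly at the barrier top would
double the measured rate (the committor there is ½) and would be
inconsistent with the Kramers values above; the boundary is configurable.
The extra downhill-slide time this adds (~2×10² τ) is negligible against
the mean first-passage times studied (≥ 4×10⁴ τ).

**WT-MetaD engine.**  Gaussian hills of width σ = 0.5 and initial height
1 k_BT are deposited at the walker position every Δ steps; heights decay
as h·e^{−V/k_BΔT} with biasfactor λ = (T+ΔT)/T = 2 by default (λ = ∞
gives untempered constant heights).  Forces are looked up from a uniform
CV grid (spacing σ/25) holding the accumulated bias; deposited heights and
logged bias values use exact hill sums, so they can be cross-checked
bitwise against the pure-Python hill engine.

**OPES flooding engine.**  A kernel-density estimate of the CV
distribution is updated every Δ steps with fixed-width Gaussian kernels
(no kernels inside the exclusion region).  With p̂ the KDE normalized by
its maximum and ε = e^{−βΔE/(1−1/λ)}, the bias is
V = (1−1/λ)β⁻¹ log((p̂(1−ε)+ε)/ε): zero where the KDE vanishes, exactly
ΔE at the mode, so sup V − inf V ≤ ΔE holds by construction.  This is the
standard flooding bias up to the (1−ε) factor and an additive constant.
The KDE is unweighted and uncompressed — adequate for a 1D benchmark,
not a production OPES implementation.

**Bias-trace resolution.**  The experienced bias V(x(t), t) is logged
every 10 τ (never sparser than one deposition interval), at every
deposition and at termination.  Logging only at depositions proved too
coarse for slow deposition paces: the sampled bias then misses most of the
walker's excursion statistics and the acceleration integrals inherit
O(0.1) log₁₀ errors.  Each trace also stores the logged positions plus
the hill/kernel history, so every logged value can be re-derived from the
bias engines exactly.

**RNG.**  Each walker seeds its own compiled-kernel RNG from a stream
spawned off the master seed, making ensembles bitwise reproducible and
independent of execution order.

## Synthetic ensembles for validation

`synthetic_biased_ensemble` draws first-passage times exactly from
S(t) = exp(−k₀∫₀ᵗ e^{γβV} dt′) under a shared bias schedule by inverting
Γ per draw (bisection to 10⁻¹² absolute).  All trajectories carry the full
schedule as their trace, so the ensemble-averaged scaling reproduces the
generating f(t) exactly and parameter recovery is a clean test of the
estimators rather than of the tail conventions.  With a monotone shared
schedule the KTR and EATR scalings coincide, so one sampler validates
both.

## Numerical choices

* Quadrature for Γ: trapezoid on the recorded grid by default; a left
  rectangle rule is provided and is exact for stepwise (deposition-held)
  bias.  Partial segments interpolate the *exponent* linearly.
* Overflow: all exponents γβV are capped at 700 before exponentiation;
  ensemble averages use log-sum-exp.
* Ties in event times step the empirical CDF by k/N; the CDF is
  right-continuous and censored records enter the denominator only.
* Degeneracy threshold: likelihood-scan spread below
  `optimizer_tolerance · (1+|log L|)` sets the degenerate flag instead of
  failing.
* The γ grid scan makes the profile optimum deterministic even when the
  likelihood is flat or multimodal; the refinement is a bounded scalar
  minimization between the best grid point's neighbours.

## Problem sizes used in the test suite

The suite validates the simulator against theory at reduced barriers
(ΔU = 2–4 k_BT, 100–500 walkers), where first-passage statistics are
cheap; the closed form is checked against the exact double integral
separately for ΔU up to 10 k_BT, so nothing is lost by validating the
dynamics at low barriers.  The full ΔU = 8 k_BT unbiased benchmark
(~10¹⁰ integrator steps) runs in minutes through the CLI and is shown in
the README.  The WT-MetaD deposition-pace study uses the reference
conditions (ΔU = 8 k_BT, N = 100, paces 10–10⁴ τ).  "Within bootstrap
error" is asserted as three bootstrap standard deviations with an absolute
floor of 0.05 (in log₁₀k₀ or γ) to guard zero-variance degenerate cases,
chosen before the tests were run.

## Known limitations

* Single-barrier escape only: no multi-state or multi-barrier survival
  models, and a single scalar γ (no per-CV efficiencies).
* The 1D simulator emulates the time-dependent-bias structure of real
  enhanced-sampling data — it has no orthogonal degrees of freedom, so a
  fitted γ < 1 on simulator data reflects estimator/finite-sampling
  behaviour, not CV quality.  Passing tests show the estimators invert
  their own generative model and the 1D benchmark; they cannot show that
  γ ranks CV quality on a real molecular system.
* The likelihood treats the pre-exponential factor as bias-independent;
  the overbiasing regime (γ·maxV above the true barrier) is out of scope.
* Euler–Maruyama first-passage times carry an O(√dt) boundary bias;
  at dt = 0.01 τ this is well below the sampling error at the ensemble
  sizes used.
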