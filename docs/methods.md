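# Methods

## Model

The delta–three-parameter lognormal (DTPLN) law describes nonnegative
observations with exact zeros: `X = 0` with probability δ, otherwise
`X = a + exp(Y)` with `Y ~ N(μ_Y, σ²_Y)`.  Parameters and units (for
the rainfall application): δ ∈ (0, 1) dimensionless; `a ≥ 0` in mm/wk
(the lower bound of the positive support); μ_Y in log-mm, σ²_Y > 0 in
squared log-mm.  The inferential target is the log-mean
`θ = ln(1 − δ) + ln(a + exp(μ_Y + σ²_Y/2))`, so `exp(θ)` is the
distribution mean.  δ = 0 is accepted (pure three-parameter lognormal);
δ = 1 is rejected (θ undefined).  Zeros are detected by exact equality;
values in `(0, a]` are legal under the CDF but rejected by estimation —
they indicate a misspecified threshold.

## Point estimation

* δ̂ = n₀/n (the binomial MLE over the zero/positive split).
* **Threshold.**  â solves the Cohen–Whitten modified-moment system:
  with μ(a), σ²(a) profiled out by matching the sample mean and sample
  variance of the positives to the shifted-lognormal moments, the
  remaining equation matches the smallest observation to the smallest
  order statistic of the fitted law.  Two variants of that third
  condition are implemented: on the log scale,
  `ln(x₍₁₎ − a) = μ + σ·E[Z₍₁:n₁₎]` (default), and on the raw scale,
  `x₍₁₎ = E[X₍₁₎]`.  On the embedded rainfall records these give
  1.7604 and 1.0780 respectively; the log-scale variant with the
  `n₁ − 1` variance divisor reproduces the published threshold for this
  dataset and is the default.  `E[Z₍₁:n₁₎]` and `E[X₍₁₎]` are computed
  by 400-point Gauss–Legendre quadrature on [−12, 12] (cached per n₁).
  The root search is a bracketed Brent solve on `[0, x₍₁₎(1 − 10⁻⁹)]`
  with absolute tolerance 1e−10.  When the residual has no sign change
  (a small-sample pathology seen occasionally in simulation), the
  estimator falls back to â = 0 with a warning; the simulation engine
  counts these events.
* **Location/scale.**  μ̂_Y and σ̂²_Y are the mean and variance of
  `ln(x − â)` over the positives.  The unbiased divisor `n₁ − 1` feeds
  every interval method; the MLE divisor `n₁` is retained for
  likelihood identities.
* **Threshold variance.**  The asymptotic variance
  `σ̂²_â = σ² exp(2μ − σ²) / (n₁[e^{σ²}(1 + σ²) − 2σ² − 1])` at the
  plug-in estimates.  This closed form is isolated in one function: it
  noticeably overstates the finite-sample variance of the
  modified-moment estimator at small n₁ (see Limitations), and is the
  single largest driver of GCI/MOVER width at n = 30.

The log-likelihood omits the additive binomial coefficient
`ln C(n, n₀)`; differences of log-likelihoods are unaffected.

## Bayesian intervals (NI1, NI2)

Both noninformative priors yield posteriors with independent blocks
given the data summaries (n₀, n₁, μ̂_Y, σ̂²_Y):

| block | NI1 | NI2 |
|---|---|---|
| δ | Beta(n₀ + 1/2, n₁ + 3/2) | Beta(n₀ + c, n₁ + c), c = 1/3 + w²_{α/2}/6 |
| μ_Y | t_{n₁−1}(μ̂, σ̂²/n₁) | t_{n₁−1}(μ̂, σ̂²/n₁) (see note) |
| σ²_Y | InvGamma(n₁/2, (n₁−1)σ̂²/2) | InvGamma((n₁−1)/2, (n₁−1)σ̂²/2) |

θ draws are assembled elementwise and the intervals are the
equal-tailed quantiles or the shortest window (HPD).  Inverse-gamma
draws are reciprocals of gamma draws; Student-t draws are
location-scale transforms of standard-t draws.  Default m = 5000 draws
per interval.

**NI2 location scale.**  A literal reading of the normal–gamma
marginalization gives the squared scale `σ̂²/(2n₁)`; the standard result
is `σ̂²/n₁`.  Only the standard scale reproduces the benchmark ordering
of NI2 relative to NI1 (slightly wider intervals with slightly higher
coverage), so it is the default; `NI2Config(mu_scale="as-printed")`
selects the halved form.

**Threshold posterior.**  Under either prior the marginal kernel for
`a` is `∏(xᵢ − a)^{-1}`, obtained by treating the profiled variance as
constant in `a`.  That kernel is monotone increasing on `[0, x₍₁₎)` and
non-integrable at `x₍₁₎`; truncating at `x₍₁₎(1 − 10⁻⁶)` makes it
proper, but a correct sampler then concentrates essentially all mass
against the truncation point, which biases θ upward and collapses
frequentist coverage (to ≈0.6 in the large-threshold scenarios).
Retaining the `a`-dependence of the profiled variance gives the proper
marginal `∏(xᵢ − a)^{-1}·σ̂²(a)^{-n₁/2}`, which instead spreads over
most of `[0, x₍₁₎)` and roughly doubles interval length.  Neither
matches the calibrated behavior these intervals are known for, which
corresponds to a degenerate threshold posterior at the point estimate.
The default is therefore `a_posterior="plugin"` (all θ draws use â);
`"metropolis"` samples the literal truncated kernel.

**Metropolis sampler.**  Because the kernel's mass spreads over many
orders of magnitude of the gap `x₍₁₎ − a`, a random walk in `a` mixes
poorly; the chain walks in `u = ln(x₍₁₎ − a)` with the Jacobian folded
into the target.  500 burn-in iterations with the proposal scale
adapted every 50 iterations toward 30–50% acceptance; a tuning failure
(acceptance outside [0.05, 0.95] at m ≥ 1000) raises an error.  Fixed
seeds give bitwise-identical chains.

**Interval conventions.**  Equal-tailed bounds are empirical quantiles
with linear order-statistic interpolation (position `(m−1)q + 1`).  The
HPD is the narrowest window of `k = ⌈level·m⌉` consecutive sorted
draws, ties broken toward the smaller lower bound.  With these
conventions the HPD is never wider than the equal-tailed interval at
the draw counts used here (multiples of 100); for arbitrary m the two
quantile granularities (`k − 1` whole gaps vs `(m−1)·level`
interpolated units) can disagree by a fraction of one inter-draw gap,
so the dominance is not an identity for every m.

## Generalized confidence interval

Component generalized pivotal quantities, per draw:
`R_a = â − T·σ̂_â` with `T ~ t_{n₁−2}`;
`R_δ = sin²(arcsin√δ̂ − K/(2√n₁))` with `K ~ N(0,1)` (variance
stabilization over the positive-part count n₁ as specified; dividing by
`√n` is available as an option);
`R_σ² = (n₁−1)σ̂²/U` with `U ~ χ²_{n₁−1}`; and
`R_μ = μ̂ − W·√(R_σ²/n₁)` with `W ~ N(0,1)`.
`R_θ` follows the θ formula; draws with
`R_a + exp(R_μ + R_σ²/2) ≤ 0` (possible because T is heavy-tailed) are
rejected and redrawn, with the count recorded and an error if
rejections exceed 5% of m.  The GCI is the equal-tailed quantile pair
of the `R_θ` draws.  Because the GPQs depend on the data only through
the estimates, identical estimates and seeds give identical draws.

## MOVER interval

`θ = ln θ₁ + ln θ₂` with `θ₁ = 1 − δ` and `θ₂ = a + exp(μ_Y + σ²_Y/2)`.
Component intervals: a Wilson score interval for the positive
proportion, taken on the log scale; `â ∓ t_{α/2,n₁−2}·σ̂_â` for the
threshold; and for `μ_Y + σ²_Y/2` the normal-mean half-width combined
in quadrature with a chi-square-based half-width for the variance half.
The `ln θ₂` interval is assembled by the square-root-of-squared-
distances (MOVER) rule inside `θ̂₂`, then combined with the Wilson
interval by the same rule.  The inner combination mixes a
threshold-scale distance with a log-scale interval; the default
measures the second component's distances on the original scale
(between `exp(μ̂ + σ̂²/2)` and the exponentiated bounds), which is
dimensionally consistent with `a + exp(·)`; `component2_scale="log"`
uses the log-scale bounds verbatim.  If the inner lower distance
reaches `θ̂₂` the logarithm is undefined; this is raised as an error
(and counted as a method failure in simulation), never clamped.  The
construction is fully deterministic.

## Monte Carlo benchmark engine

Per replicate: sample from the DTPLN law, fit, build each requested
interval, and score coverage of the true θ (recomputed from the
generating parameters) and width on the θ scale.  Replicates get
deterministic child seeds spawned from the scenario seed, with separate
streams per method family, so results are independent of scheduling.
Degenerate replicates (n₁ < 3 or all positives equal) are redrawn and
counted; per-method failures are excluded from that method's aggregates
and a scenario aborts when any method fails in more than 2% of
replicates.  The generator's reference grid crosses
a ∈ {1, 5, 15}, n ∈ {30, 50, 100}, δ ∈ {0.1, 0.3, 0.5},
σ²_Y ∈ {0.3, 0.5, 0.8, 1.0, 2.0} at μ_Y = 2, with 5000 replicates ×
5000 draws at full scale.  The packaged acceptance run and tests use
reduced sizes — 2500–3000 replicates of 2000 draws at six selected
cells — which track the full-scale coverage values to within Monte
Carlo error (CP standard error ≈ 0.004 at 3000 replicates).

## Model screening

Candidate families for the reduced positives `x − â`: Cauchy,
exponential, gamma, logistic, lognormal, normal, location-scale
Student-t, Weibull, ML-fitted with the location pinned at zero for the
positive-support families so that k counts only free parameters.
`AIC = −2 ln L + 2k`, `BIC = −2 ln L + k ln n` (the standard penalty;
the identity `BIC − AIC = k(ln n − 2)` holds for every emitted fit).
Absolute AIC/BIC values depend on fitting conventions; the asserted
surface is the ranking, which puts the lognormal first on the reduced
rainfall data by both criteria.

## What the generator emulates, and what it does not

`rdtpln` reproduces the DTPLN data-generating process exactly:
independent Bernoulli zeros and iid shifted-lognormal positives.  Real
rainfall networks violate independence (spatial correlation between
stations), stationarity (seasonal drift), and exact zero inflation
(detection limits rather than true zeros).  Passing tests therefore
demonstrate correctness of the estimators and interval procedures under
the model's own assumptions — not robustness to spatial dependence or
misspecification, which are out of scope.

## Known limitations

* The closed-form threshold variance overstates the sampling
  variability of the modified-moment â at small n₁ (at n = 30 cells,
  plug-in values average ≈3× the empirical variance).  GCI and MOVER
  inherit this as conservative coverage (≈0.99 at nominal 0.95) and
  inflated expected length at small samples; at n = 100 the effect is
  minor.  The MOVER expected length at small n is therefore larger than
  the best published behavior of this interval family; its coverage is
  unaffected.
* The literal threshold-posterior kernel is degenerate (see above); the
  plug-in default trades posterior uncertainty in `a` for calibration,
  and understates total uncertainty when the threshold is genuinely
  poorly determined.
* HPD-vs-equal-tailed width dominance is granularity-limited for draw
  counts that are not multiples of the coverage level's denominator.
* All methods require n₁ ≥ 3 and non-constant positives; δ̂ at the
  boundary (n₀ = 0) is handled, δ = 1 is not modeled.
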