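# Methods

## Model

A sample x₁,…,xₙ of strictly positive values is modelled as i.i.d.
Birnbaum–Saunders BS(α, β): the transform Z = (√(X/β) − √(β/X))/α is
standard normal. The density is

f(x; α, β) = [1/(2αβ√(2π))] · ((β/x)^{1/2} + (β/x)^{3/2}) ·
exp(−(x/β + β/x − 2)/(2α²)),  x > 0,

and the p-th percentile is θ_p = (β/4)(α z_p + √(α² z_p² + 4))² with
z_p = Φ⁻¹(p). Two exact consequences are used as test oracles throughout:
θ_{0.5} = β for every α, and θ_p · θ_{1−p} = β².

The inferential target is a two-sided 100(1−γ)% interval for θ_p. All four
constructions treat the data as a single homogeneous i.i.d. sample; none
model serial dependence, seasonality or covariates, all of which are present
in real pollutant series (see Limitations).

## Maximum likelihood

The shape is profiled out in closed form: α̂²(β) = x̄/β + β·(1/x)̄ − 2
(nonnegative by the AM–GM inequality). The profile log-likelihood is then
maximized over log β by bounded Brent search on [log min x, log max x],
widening the bracket geometrically if the optimum pins to an endpoint.
We chose profile *maximization* over a root search on the profile score
because it needs no derivative, cannot converge to a minimum, and the
bracket endpoints are natural. Constant samples are rejected: they drive
α̂ → 0 and make the downstream pivotal quantities divide by zero. The fit
agrees with an independent implementation of the same distribution
(scipy's `fatiguelife`, used only in tests) to 5+ significant digits.

## Generalized confidence interval (GCI)

With sufficient summaries I, J (means of √xᵢ, 1/√xᵢ), K, L (their sums of
squared deviations) and S₁ = Σxᵢ, S₂ = Σ1/xᵢ, a t(n−1) draw T defines a
pivot R_β as a root of Aβ² − 2Bβ + C = 0 with A = (n−1)J² − LT²/n,
B = (n−1)IJ − (1−IJ)T², C = (n−1)I² − KT²/n; the larger root is taken for
T ≤ 0 and the smaller for T > 0 (the selection undoes the squaring of the
underlying monotone t statistic). A χ²(n) draw V gives
R_α = √((S₂R_β² − 2nR_β + S₁)/(R_β V)), whose radicand is nonnegative by
AM–GM whenever R_β > 0, and R_θ follows by the percentile formula. The
interval is the empirical (γ/2, 1−γ/2) quantile pair of M simulated R_θ.

Numerical choices: draws whose quadratic has a negative discriminant or a
nonpositive selected root are resimulated (the t draw can exceed the finite
range of the underlying statistic); resimulation is capped at 100·M
attempts and the count is reported. A ≈ 0 degenerates to the linear root
C/(2B). Quantiles use linear interpolation between order statistics — with
M = 5000 the convention is worth < 0.1% of the length.

## Bias-corrected bootstrap

B parametric replicates of size n are drawn from BS(α̂, β̂) and refit; the
bias estimates b̂ = mean(estimate*) − estimate shift every replicate by
−2b̂ before the percentile map and the quantile step. The parametric scheme
is the default because the bias logic targets the fitted model; resampling
with replacement from the data is available via `parametric=False`. The
−2b̂ shift can push a corrected replicate below zero: the percentile
formula is evaluated as written for α̃ < 0, while replicates with β̃ ≤ 0
(never observed in practice at these sample sizes) are dropped and counted.

## Bayesian posterior and credible intervals

Priors: β ~ IG(a₁, b₁), α² ~ IG(a₂, b₂), defaults a₁=b₁=a₂=b₂=10⁻⁴
(near-flat; at n in the tens to hundreds the data dominate) and
ratio-of-uniforms constant r = 2. The marginal posterior kernel of β is

p(β|x) ∝ β^{−(n+a₁+1)} e^{−b₁/β} Πᵢ((β/xᵢ)^{1/2} + (β/xᵢ)^{3/2}) ·
(Σᵢ(xᵢ/β + β/xᵢ − 2)/2 + b₂)^{−((n+1)/2+a₂)},

and α² | β is exactly IG(n/2 + a₂, Σᵢ(xᵢ/β + β/xᵢ − 2)/2 + b₂), sampled as
scale/Gamma(shape). β is sampled by generalized ratio-of-uniforms: (u, v)
uniform on [0, a(r)]×[0, b⁺(r)], candidate ρ = v/uʳ, accepted when
u ≤ p(ρ|x)^{1/(r+1)}. This is exact rejection sampling — independent draws,
no chain, no convergence diagnostics needed. Acceptance rates are ~4–6% on
the fixtures and are reported.

Numerical choices: the raw kernel underflows around n ≳ 100, so all bound
finding and acceptance testing happens in the log domain with the kernel
rescaled by its maximum — the accepted distribution is invariant to kernel
scaling, which a test verifies directly. The suprema a(r) = sup p^{1/(r+1)}
and b⁺(r) = sup β·p^{r/(r+1)} are located by bounded 1-D maximization over
log β with multistarts at the 10/50/90% data quantiles; b⁻(r) = 0 because
the kernel vanishes fast enough at the origin. r = 0 is rejected (b⁺ would
be infinite). Rejected (u, v) pairs are never reused.

The equal-tailed credible interval takes the (γ/2, 1−γ/2) quantiles of the
θ draws. The HPD interval uses the sorted-window method: among all
contiguous windows of ⌈(1−γ)·M⌉ sorted draws, the shortest (ties → smallest
lower endpoint). This is deterministic given the draws and exact for
unimodal posteriors up to Monte-Carlo error; density estimation is
deliberately avoided. Note that window conventions differ by one order
statistic across implementations (arviz uses ⌊(1−γ)M⌋+1), which moves tail
endpoints by about one inter-draw spacing.

## Simulation engine

A cell (n, p, α, β) draws `reps` samples, builds every requested interval
on the *same* sample per replicate (paired design: between-method
comparisons are not inflated by independent sampling noise; whether the
original study paired methods this way is not stated, so this is our
choice), and reports per-method coverage of the true θ_p, average length,
and the binomial MC standard error √(c(1−c)/reps). Replicate k derives its
generator from child k of the master `SeedSequence`, so results are
reproducible and independent of the method subset. Bayesian cells dominate
the runtime; the engine therefore supports any replication count and always
reports the MC standard error, so scaled-down runs carry their own honest
uncertainty. Defaults mirror the reference study: 5,000 replications,
M = 5,000 pivotal draws, B = 500 bootstrap replicates, M = 1,000 posterior
draws, β = 1.

Problem sizes used in the shipped checks: the GCI column is verified at the
full 5,000 × 5,000 scale (a few seconds per cell, vectorized over draws);
the bootstrap/Bayes/HPD comparison runs one representative cell at 500
replications with 3 scaled MC standard errors (±0.03) as the band.

## Model comparison

Seven families are fit by ML — closed form for normal (variance divisor n),
log-normal (same on log x) and exponential; scipy optimizers with the
location pinned at 0 for Weibull (shape, scale) and gamma (shape, rate);
Cauchy (location, scale) and Birnbaum–Saunders numerically — and ranked by
AIC = 2k − 2 log L with k = 1 for the exponential and k = 2 otherwise. The
change-of-variables identity AIC_lognormal(x) = AIC_normal(log x) + 2Σlog x
is asserted as a cross-check. A family whose optimizer fails is reported as
missing rather than aborting the table.

## Known limitations

- I.i.d. modelling of an autocorrelated daily series: coverage statements
  transfer to real monitoring data only approximately.
- The simulation grid fixes p = 0.5 (where θ = β and the GCI reduces to an
  essentially exact t-pivot inversion); the engine accepts any p, but
  coverage for extreme percentiles at small n is not characterized here.
- The bias-corrected bootstrap keeps the estimator exactly as defined even
  when the −2b̂ shift produces a negative corrected shape; this is the
  printed estimator, not a fix for it.
- Bundled fixtures transcribe the published data table verbatim, including
  one Lampang pair ("16.91, 8.2") that looks like a typesetting artifact;
  8.2 is consistent with the published sample minimum, so it is retained.
- The synthetic sampler generates exactly the model's normal-transform
  variates; it emulates the study's data-generating conditions, not real
  pollutant dynamics (no dependence, no seasonality, no detection limits),
  so passing coverage checks validate the interval constructions under the
  model, not field performance.
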