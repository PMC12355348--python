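# Methods

## Scope and data model

The package synthesises published habitat-specific estimates of the
autochthonous share of soil organic carbon in saltmarsh, mangrove and
seagrass wetlands. One *estimate* is a reported autochthonous mean (%), a
typed variability measure, the design covariates (habitat, climate,
mixing-model method, soil-depth midpoint, number of end-members, spatial
replication), and optionally a per-source contribution breakdown. Estimates
nest in *studies* (publications), which define the random-intercept grouping
of the meta-regression; a configuration switch (`ModelSpec.group_by`) allows
grouping by estimate instead, since compilations sometimes treat each
habitat × tracer combination within a publication as its own unit.

## Variability harmonisation

Studies report dispersion as SD, SE, 95% CI or variance. All are converted
to an "adjusted SD" under normality: SE × √n, √n·(upper − lower)/(2·z₀.₉₇₅),
or √variance, with n the spatial replication behind the reported mean. The
CI conversion assumes a symmetric normal CI of a mean over n replicates.
Other conventions (ranges, quartiles) are rejected at ingest rather than
guessed — silent misestimation of a variance propagates into every
downstream weight, so failing loudly is the safer default.

## Log-ratio construction

Each harmonised (mean m, SD s) pair defines Normal(m, s) truncated to the
open interval (0, 100). The package draws 10⁶ values aᵢ by inverse-CDF
sampling (draws rounding to exactly 0 or 100 in floating point are
resampled, keeping ln finite without biasing the open interval), sets the
allochthonous complement to 100 − aᵢ, and summarises ln(aᵢ/(100 − aᵢ)) by
its mean θ̂ and SD σ̂. Reported means of exactly 0% or 100% are clamped to
0.1 / 99.9 with a warning — the procedure is undefined at the boundary, and
clamping preserves the record visibly rather than discarding it. A
deterministic quadrature oracle computes the same two moments by adaptive
integration in probability space (u ∈ (0,1) mapped through the truncated
normal's inverse CDF, which stays well-conditioned even for near-degenerate
SDs); it exists purely to validate the sampler in tests, to relative
tolerance 10⁻⁸.

Reproducibility contract: each record's RNG substream is keyed by
SHA-256(master seed, estimate id), so batches are order-independent and a
record's log-ratio is identical whether processed alone or with others.

## Hierarchical meta-regression

    θ̂κ ~ Normal(μκ, √(σ̂κ² + σ²)),   μκ = xκᵀβ + ζ_s(κ)·σ_between
    β_t, ζ_s ~ Normal(0, 1)
    σ_between, σ ~ Normal(0.5, 0.1) truncated to (0, ∞)

Continuous covariates are centred and scaled by in-sample mean and SD
(ddof = 1), stored for prediction; categorical covariates are dummy-coded
against reference levels mangrove / tropical / bayesian. Dummy columns that
are constant in-sample are dropped with a warning; a constant continuous
covariate is an error. The scale priors are written truncated explicitly —
the untruncated prior puts only ~3×10⁻⁷ mass below zero, so this is a
normalisation nicety, not a substantive choice. The intercept takes the same
Normal(0, 1) prior as the other coefficients. Note the scale priors are
informative (SD 0.1): posteriors for σ_between and σ are pulled toward 0.5
whenever the data only weakly identify them, which is visible in recovery
simulations whose true scales sit away from 0.5. That is a property of the
stated prior, not of the sampler.

### Sampler

Conditional on (σ_between, σ) the model is linear-Gaussian, so `fit_mcmc`
is a blocked Gibbs sampler:

- β | rest: multivariate normal via Cholesky of XᵀWX + I, W = diag(1/(σ̂ᵢ²+σ²));
- ζ | rest: independent normals per study;
- σ_between | rest: it enters the mean linearly (μ = Xβ + σ_between·ζ_s(κ)),
  so its conditional is a zero-truncated normal, sampled by inverse CDF;
- σ | rest: univariate slice sampling (stepping-out width 0.25, then
  shrinkage), since it enters the variance.

Defaults are 4 chains × 10,000 sweeps with 5,000 discarded as warmup
(20,000 retained draws). Chains are seeded from spawned `SeedSequence`
streams, so a fixed seed reproduces draws exactly. There is no
adaptation phase and no divergence concept; the sampler is validated by
(i) agreement of the posterior mean of μ with dense-grid integration on a
small problem (tolerance 0.02), (ii) split-R̂ ≤ 1.01 and bulk ESS ≥ 400 on
the default fixtures, and (iii) parameter-recovery simulations.

### Diagnostics and derived quantities

`gelman_rubin` implements the classic potential scale reduction factor
(√(((n−1)/n·W + B/n)/W); `split=True` halves chains first and is what the
fit summary reports). `effective_sample_size` uses FFT autocovariances
averaged across chains with Geyer's initial-monotone truncation of paired
autocorrelation sums. Between-study fold-variation is e^(2σ_between) per
draw, summarised by median and central 95% interval. Bayesian R² per draw s
is V_fit,s / (V_fit,s + V_res,s), with V_fit the across-observation variance
(ddof = 1) of μ^(s) and V_res the mean modelled residual variance
mean(σ̂²) + σ_s².

## Model evaluation

Pointwise log-likelihoods feed PSIS-LOO: importance ratios 1/p(θ̂ᵢ|draw) are
smoothed per observation by a generalized-Pareto fit (Zhang–Stephens
empirical-Bayes estimator) to the largest min(20%, 3√S) ratios (minimum tail
5), with smoothed weights capped at the raw maximum, and the Pareto shape k
reported per observation (k > 0.7 flagged; no moment-matching refits). The
implementation reproduces arviz's `psislw` to machine precision on shared
inputs and matches exact refit-LOO within 0.03 nats on conjugate toys.
Model comparison reports Σ elpd differences and the SE of the pointwise
differences (√(n·var)); no hard selection threshold is applied.

Posterior predictive checks replicate datasets from
Normal(μ^(s), √(σ̂² + σ_s²)) and compare mean/SD/min/max against the
observed statistics. PIT residuals are randomized-quantile residuals:
PIT_i = fraction of replicates below θ̂ᵢ, randomized at ties. For PIT the
replicates *re-draw the study intercepts* from Normal(0, σ_between) rather
than conditioning on the fitted ζ: the conditional predictive shrinks
toward each study's own data and concentrates PIT near 0.5, so uniformity
under a correct model — the property the diagnostic is for — only holds for
the unconditional form. `posterior_predictive` keeps the conditional form
as its default (`resample_groups=False`).

## Source attribution

Per habitat × source cell, contributions are pooled as the unweighted mean
and SD of per-dataset means (no replication weighting — none is defensible
without the original per-dataset variances on a common basis). Bootstrap
densities draw 1,000 values per dataset from Normal(mean, SD) truncated to
[0, 100], pool across datasets, and estimate a Gaussian KDE with a plug-in
bandwidth (1.06·min(SD, IQR/1.349)·n^(−1/5)) reflected at both boundaries,
plus empirical quantiles. A mixture-CDF inversion oracle validates the
bootstrap quantiles in tests.

Two-source δ¹³C mixing solves δ_M = f·δ₁ + (1−f)·δ₂ with delta-method
variance Var(f) = [s_M² + f²s₁² + (1−f)²s₂²]/(δ₁−δ₂)², each s² the squared
standard error of a signature mean. Fractions outside [0, 1] are reported
with an extrapolation flag, not clipped. The exact ratio-of-normals
distribution has no finite variance (the denominator's density is positive
at zero), so Monte-Carlo validation compares the delta SE against the
central 68.27% quantile width of 10⁶ simulated fractions — the bulk-scale
analogue of one SD — where agreement is within 2% at the tested
signal-to-noise. Only two-source mixing is implemented; multi-source
Bayesian mixing is out of scope.

## Synthetic compilation generator

The generator is first-class, tested code that emulates the compilation's
structure: 110 estimates in 78 studies (every study at least one estimate);
habitat counts 20/34/56 (saltmarsh/mangrove/seagrass); tropical fractions
0 / 0.83 / 0.43 per habitat; method mix 0.45/0.40/0.15
(standard/bayesian/other — a value the compiled literature does not pin
down, chosen once as realistic for this field where standard mass-balance
models dominate older studies); depth midpoints lognormal matched to mean
0.20 m and SD 0.27 m (right-skewed and nonnegative, as mean < SD implies);
replication 2 + round(lognormal) clipped to [2, 35] with median ≈ 6;
end-member counts 2 + Poisson(1.8) clipped to 10; variability kinds mixed
0.50/0.20/0.15/0.15 (sd/se/ci95/variance); per-estimate log-ratio sampling
SDs lognormal(ln 0.25, 0.4). Default truth: σ_between = 0.65,
σ_resid = 0.3, and fixed effects of magnitude 0.05–0.5 in the directions the
fitted compilation reports (more allochthonous carbon under saltmarsh and
seagrass, in temperate sites, at depth; more autochthonous under standard
and other methods and at higher replication). These are the package's
synthetic study conditions, not measured ground truth.

Generation happens natively on the log-ratio scale — the model's own
generative process — and back-transforms each (θ̂, σ̂) to the reported
percent scale by *exactly inverting* the truncated-normal log-ratio moment
map (400-node Gauss–Legendre moments inside a 2-D root find, started from
the inverse-logit/delta-method approximation, which also serves as the
fallback and as the exact shortcut for σ̂ < 10⁻⁶). The first-order
delta-method back-transform was measurably lossy: pipelines run on
delta-generated data recovered σ_resid ≈ 0.40 against a truth of 0.30, an
artefact of the approximation rather than of the estimator. With exact
inversion the full pipeline (harmonise → Monte-Carlo log-ratio → fit) sees
data that follow the stated model up to Monte-Carlo error.

What the generator does **not** emulate: real tracer chemistry and
signature overlap; correlation between σ̂κ and covariates (independent by
default, configurable); non-normal reported dispersions; selection effects
in the literature. Passing recovery tests therefore demonstrates the
estimator and pipeline are sound under the stated model, not that the model
is adequate for any particular real compilation.

## Problem sizes in tests and reproduction runs

The acceptance script runs the full production configuration (110 estimates,
10⁶ Monte-Carlo draws per log-ratio, 4 × 10,000 MCMC sweeps) — the Gibbs
sampler makes this cheap. The test suite scales simulations to what the
checks need: recovery uses 20 replicates at K = 40 studies / n = 60
estimates with 2 × 2,000 sweeps and 10⁵ log-ratio draws (tolerances widened
by √10 accordingly); calibration checks (PPC, PIT, LOO comparison) use
10-replicate batches of n = 40 / K = 20 fits at 2 × 800 sweeps. At these
sizes a per-coefficient median bias over 20 replicates has standard error
≈ 0.08, so bias is assessed on the biases pooled across coefficients and
replicates ("centered on zero"), while per-parameter tables remain available
from `coverage_summary`.

## Known limitations

- The scale priors Normal(0.5, 0.1) are strongly informative; analyses of
  compilations whose heterogeneity is far from 0.5 on the log-ratio scale
  inherit that pull. They are kept as stated because they define the model
  this package implements.
- PSIS-LOO Pareto-k values above 0.7 are flagged but not repaired.
- The CI→SD conversion assumes normal CIs of means; bootstrap or quantile
  intervals reported by primary studies would be misconverted (and should be
  entered as `sd` after manual conversion).
- The Gibbs sampler relies on the specific likelihood structure; extending
  the model (e.g. non-normal likelihoods, covariate-dependent σ̂) requires a
  different sampler, not a new prior.
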