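# bluecarbon-meta

Where does the organic carbon buried in coastal wetland soils come from —
the habitat-forming plants themselves (autochthonous), or the surrounding
seascape (allochthonous)? Published mixing-model studies of saltmarsh,
mangrove and seagrass soils answer this one site at a time, each with its
own tracers, end-members, replication and reporting conventions. This
package implements a complete meta-analytic pipeline for synthesising such
estimates: it harmonises heterogeneous variability reports, converts each
estimate to a log-ratio effect size with propagated uncertainty, fits a
Bayesian hierarchical measurement-error meta-regression, evaluates the model
(PSIS-LOO, posterior predictive checks, PIT residuals, Bayesian R²), and
pools per-source contributions into bootstrap densities. A synthetic-data
generator with known ground truth drives every stage without downloads, so
the statistical machinery is testable end to end.

It is written for quantitative ecologists and meta-analysts working on blue
carbon provenance, but the model is a generic random-effects meta-regression
with known within-estimate variance.

## The model

Each independent estimate κ contributes a log-ratio mean
θ̂κ = mean ln(auto% / allo%) and its known sampling SD σ̂κ, obtained by
drawing 10⁶ values of the autochthonous percentage from a normal
distribution truncated to (0, 100) and taking ln(a / (100 − a)) of each.
The meta-regression is

    θ̂κ ~ Normal(μκ, √(σ̂κ² + σ²))
    μκ  = xκᵀβ + ζ_s(κ) · σ_between
    β_t, ζ_s ~ Normal(0, 1)
    σ_between, σ ~ Normal(0.5, 0.1) truncated to (0, ∞)

with fixed effects for habitat, climate, mixing-model method (dummy-coded
against mangrove / tropical / bayesian reference levels), and centred-scaled
depth midpoint, end-member count and replication; ζ_s are per-study
standardized random intercepts (non-centred parameterisation), σ_between the
between-study heterogeneity and σ a residual SD. Because the model is
linear-Gaussian given the two scales, it is fitted by a blocked Gibbs
sampler (conjugate updates for β, ζ and σ_between; slice sampling for σ),
validated against brute-force grid integration and standard convergence
diagnostics. The quantity e^(2·σ_between) is reported as the implied
fold-variation in the auto:allo ratio between comparable studies.

## Worked example

The numbered scripts under `analysis/` run the full study on the synthetic
compilation (110 estimates, 78 studies):

```
python analysis/01_simulate_compilation.py --seed 1
python analysis/02_harmonize_logratios.py  --seed 1
python analysis/03_fit_meta_regression.py  --seed 1
python analysis/04_evaluate_model.py       --seed 1
python analysis/05_source_densities.py     --seed 1
```

Step 03 prints the posterior summary, ending with:

```
between-study SD 0.52 [0.39, 0.64] -> ~2.8-fold variation in auto:allo after fixed effects
Bayesian R2 0.61 [0.46, 0.72]
convergence: all clear
```

i.e. after accounting for habitat, climate, method and the sampling-design
covariates, two otherwise comparable studies still differ by roughly
threefold in their autochthonous:allochthonous ratio (the generating truth
for this run was σ_between = 0.65). Step 04 compares against the
intercept-only model:

```
elpd difference 10.7 +- 5.2 (favors the full model)
PIT uniformity: KS statistic 0.075, p = 0.54
```

and step 05 pools the per-source table, recovering the configured
cross-habitat subsidies (e.g. `mangrove -> seagrass soils: 25% (n=56)`).

The same pipeline runs from a single entry point (`bluecarbon run
--synthetic --seed 1 --out results/run`) or on a real compilation CSV
(`bluecarbon run --compilation compilation.csv`); see `bluecarbon --help`
for the per-stage subcommands and the documented CSV schemas in
`bluecarbon.compilation`.

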