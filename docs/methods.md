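# Methods

This note documents the models, their numerical treatment, the synthetic
data the tests rely on, and the design choices made where the design was
genuinely open. It states no empirical result the test suite or the
acceptance script does not itself compute.

## Growth from tagging increments

### Model

Tag-recapture data carry growth information as (release length L₁,
increment ΔL, time at large Δt) triples. The VBGF is reparameterized by
the mean annual growth increments (g_α, g_β) at reference lengths
α = 100, β = 130 cm TL, which must lie inside the observed length range
and have distinct growth rates but are otherwise arbitrary; the package
exposes them as configuration. The expected increment and the conversion
to (L∞, k) are closed-form (README). The observation density is a
two-component mixture:

    f(ΔL) = (1 − p)·N(ΔL; μ + m, σ²ᵢ + s²) + p/R,
    σᵢ = ν·μᵢ,   R = range of observed increments.

- ν ≥ 0: coefficient of variation of individual growth variability —
  spread proportional to expected growth, so residual spread should rise
  with predicted growth and fall with release length (checked by
  `residual_diagnostics` via Spearman rank correlations).
- (m, s): net measurement error on the increment (mean, SD in cm). s
  enters the increment variance once; the alternative convention of
  doubling it (error on each of two length measurements) is rejected
  here — s is defined as the error of the *increment*, which is what the
  data identify.
- p: outlier contamination, uniform over the observed increment range
  (data-dependent R, recomputed per dataset).
- (u, w): seasonal amplitude and phase; calendar times are warped by
  t′ = t + (u/2π)sin(2π(t − w)) before Δt is formed. The warp integrates
  to zero over whole years.

### Numerical choices

- When μᵢ ≤ 0 (release at or above L∞; shrinkage is not modelled) the
  growth-variability SD is floored at ε = 0.1 cm so the density stays
  proper; with ν = 0 the floor is not applied.
- Optimiser: L-BFGS-B on the free parameters with box bounds, from
  moment-based starting values (regression of annual growth rate on
  release length, evaluated at α and β) plus ±20% jittered restarts
  (default 5, seeded). Invalid regions (g_α ≤ g_β, undefined k) return a
  large penalty.
- Standard errors: inverse central-difference Hessian at the optimum
  (Wald); a singular Hessian yields NaN SEs with a warning rather than
  failure.
- AIC counts only free parameters. Time at large is exact day count /
  365.25; the 150-day minimum-time filter is inclusive.
- Male-only fits are refused below n = 25 (too few male recaptures to be
  stable); female-only and combined fits are supported.

### Model selection

Stepwise likelihood-ratio comparisons for declared nested pairs:
log-likelihood gain > 1.92 for one extra parameter, > 3.0 for two or
more, plus an AIC table with a ΔAIC > 3 preference rule. The default
ladder frees s; then ν; then m; then p; then (u, w).

## Jolly–Seber survival

### Model

Annual occasions (the nine calendar years of the emulated study design).
Latent state per individual-year: not-yet-entered, alive, dead. Entry
happens at most once (probability γ_t given still available), survival
between consecutive years is constant φ (the estimand: one annual
apparent-survival rate), detection while alive is occasion-specific p_t
(a constant-p variant is available by configuration). The observed
matrix is augmented with all-zero pseudo-histories (default 3× the
observed count) so the superpopulation size becomes an inclusion
problem. Priors are U(0,1) throughout.

### Sampler

Parameters are updated by Metropolis-within-Gibbs against the
*collapsed* likelihood — the forward algorithm over unique capture
history patterns with latent states summed out — using logit-scale
random-walk proposals whose steps adapt toward 44% acceptance during
burn-in only (fixed afterwards, preserving detailed balance). The
superpopulation size is drawn exactly each iteration: an augmented
all-zero row entered the population with probability
1 − Πₜ(1 − γ_t)/P(all-zero history). Latent trajectories, when needed
(the no-re-entry invariant check), are drawn exactly by
forward-filtering backward-sampling.

This kernel was chosen over the classical single-site latent-state Gibbs
with conjugate Beta updates: both were implemented and validated against
an exact enumeration posterior on a tiny problem, but the conjugate
scheme mixes slowly in the weakly identified entry parameters at reduced
iteration budgets, while the collapsed scheme reaches r̂ < 1.1 at
3 chains × 5,000 iterations. Default run configuration is
3 × 25,000 with 5,000 burn-in; tests and examples scale this down. A
mandatory seed controls all chains (chain c uses seed + c).

Convergence is the classical Gelman–Rubin potential scale reduction
factor (between/within-chain variance ratio), reported per monitored
parameter; any r̂ ≥ 1.1 flags the result non-converged (returned, not
discarded).

With uniform priors on every p_t, an *all-augmented* run is not
prior-predictive for φ: zero-detection histories genuinely favour short
lives. Pinning detection (`fix_p = 0`) makes the run data-free, and the
φ posterior then returns its U(0,1) prior (tested).

## Mortality

Direct: 1 − φ and Z = −ln φ. Indirect: Z = exp(a + b ln T_max) with the
classical teleost (1.46, −1.01) and cetacean (0.941, −0.873)
coefficients, configurable. The cetacean variant is often preferred for
sharks on demographic-similarity grounds. The comparison table flags
indirect rows as resting on Z = M, valid only in unfished systems.

**Longevity inconsistency.** The longevity formula T_max = 5·ln 2/k gives
≈ 64.2 yr at k = 0.054, while the source study reports 18.06 yr and uses
that value downstream. The package surfaces both — `longevity()` returns
the formula value; `PRINTED_TMAX` carries 18.06 — and reproduction runs
feed 18.06 to the Hoenig stage, labelled as such in outputs.

## Maturity and morphometrics

- Ogive: binomial-logit GLM (IRLS via statsmodels) of calcified (1) vs
  not calcified (0) on TL; partially calcified animals are excluded, not
  pooled. At least 10 observations per class; complete separation raises
  an error naming the separating threshold.
- Bootstrap: resamples individuals (not residuals), percentile 95%
  intervals, default 10,000 reps, mandatory seed. The resample fits use a
  vectorised two-parameter Newton solver (cross-checked against
  statsmodels to 1e-6) because per-resample GLM calls are ~1000× too
  slow at that rep count; linear predictors are clipped at ±30 so
  separated resamples saturate harmlessly.
- Maturity from maximum length: TL_m = 11.09 + 0.602·TL_max (cm), the
  elasmobranch-wide linear relation; coefficients configurable.
- Conversions: OLS for all six directed TL/FL/PCL pairs (≥ 30 complete
  pairs each); with `compare_sex`, a pooled model is compared by AIC
  against one adding sex to intercept and slope, preferred only at
  ΔAIC > 3. Note that when y is generated from x alone, sex can still
  legitimately improve *inverse* regressions by encoding the sex-specific
  predictor distribution.
- Welch t from summary statistics with Satterthwaite df; χ² sex-ratio
  test without continuity correction (counts are large).

## Synthetic data: what it emulates, what it does not

The raw individual-level data of the emulated study are unpublished, so
the generators produce inputs with exactly the statistical structure the
estimators assume, at the study's reported conditions:

- Lengths: sex-specific normals (female 146.0 ± 16.6, male
  138.7 ± 14.2 cm TL) truncated to the observed 66–180 cm range; 66%
  female.
- Growth truth: g₁₀₀ = 3.33, g₁₃₀ = 1.75 cm/yr, ν = 0.66, s = 2.87 cm
  (the study's best-fit model, both sexes).
- Times at large: gamma (shape 1.6 — a free choice giving a realistic
  right-skewed mix of short and multi-year recoveries), scaled to median
  2 yr, truncated to [150 d, 7.2 yr].
- Lengths are rounded to the 0.5 cm field grid after noise.
- Survival truth: φ = 0.74, p_t = 0.15, nine annual occasions,
  superpopulation 1500, uniform entry.
- Maturity truth: L50 = 123.2 cm, slope 0.35 /cm (10–90% transition width
  ≈ 12.5 cm, consistent with reported immature/mature mean lengths);
  partially calcified labels applied near L50 (Gaussian weight, 5 cm
  width, peak 0.3, giving roughly the reported ~8% partial fraction).

Every generator is a pure function of (truth, n, seed).

`synthetic_s1_table()` is a *calibrated stand-in* for the study's
deposited 118-recapture table (only available as a PDF): it fixes the
printed marginal structure — 118 records, 100 female / 18 male, median
time at large 2.0 yr, maximum 7.2 yr, and the printed maximum-growth
record (female, 103 → 149.5 cm over 6.8 yr) included verbatim, with
resampling so no other record exceeds that 46.5 cm increment — and draws
everything else from the default truth. A green fit on this stand-in
establishes parameter recovery under the model at the study's sample
size and composition; it does **not** reproduce the study's actual
estimates, and single-seed estimates can sit 1–2 SE from truth.

What the generators do not emulate: spatial/habitat structure,
individual heterogeneity in detection or survival, tag loss, multiple
recaptures per individual (each record is one release-recapture pair),
and age-structured entry.

## Pipeline

`reports.run_pipeline` executes the enabled stages in dependency order
on supplied or synthetic inputs, returns tables shaped like the study's
outputs plus fitted objects, isolates stage failures (bundle marked
partial), and optionally writes JSON, text tables and SVG figures.
Numeric outputs are pure functions of the configuration; re-running an
identical configuration reproduces them byte-for-byte.

## Known limitations

- The growth likelihood treats each record as independent; repeated
  recaptures of one individual would violate this (the data model keeps
  one pair per record).
- Wald SEs from the numerical Hessian can be optimistic for parameters
  near bounds (ν, p at 0); the bootstrap in the maturity stage is the
  template if profile or resampling intervals are needed for growth.
- The JS model estimates *apparent* survival: permanent emigration is
  confounded with death.
- Literature comparison values (other regions' growth parameters) are
  carried as printed, not recomputed; their unrounded sources are
  unavailable.
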