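# Methods

This note documents the statistical models `gradmeta` implements, the
defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical decisions that matter when results
are compared across implementations.

## Effect sizes (experimental track)

The effect size for a treatment-vs-control record is the natural-log
response ratio lnRR = ln(X_e/X_c), with sampling variance

v = (1/n_e)(S_e/X_e)² + (1/n_c)(S_c/X_c)².

This is the standard delta-method variance of a log ratio of independent
group means; it assumes the reported S are standard deviations (data
preparers must convert standard errors upstream — the schema is
deliberately single-meaning) and that group means are positive, which the
validator enforces because the log is otherwise undefined. Stoichiometric
ratios (C:N, C:P, N:P) enter as their own variable codes and are analyzed
on the log scale like concentrations. Both lnRR and v are invariant to a
common rescaling of measurement units, a property the test suite checks.

Percent change uses the exact back-transform (e^lnRR − 1)·100 rather than
the small-effect approximation 100·lnRR; at the effect magnitudes this
package targets (|lnRR| ≲ 0.2) the two differ by well under a percentage
point, but the exact form costs nothing.

## Random-effects pooling

Observed effects are modelled as y_i ~ N(μ, v_i + τ²). The pooled mean is
inverse-variance weighted with weights 1/(v_i + τ²), its standard error
sqrt(1/Σw), and the 95 % CI uses the normal quantile 1.96 — no
Knapp–Hartung or t adjustment, matching the plain 95 %-CI convention of
the synthesis literature this pipeline serves. Significance is "CI
excludes zero", and every pooled cell carries a four-level direction
label (positive/negative × significant/not); an exactly zero mean is
labelled positive_ns by tie-break.

τ² is estimated by REML via Fisher scoring on the restricted likelihood
(tolerance 1e-8, at most 100 iterations, truncation at zero, with a
bounded scalar search as a fallback if scoring stalls and an explicit
comparison against the τ² = 0 boundary). The DerSimonian–Laird
method-of-moments closed form max(0, (Q − (k−1))/C) is retained both as a
user-selectable method and as a hand-checkable oracle: with effects
(0.0, 0.2, 0.4) and all variances 0.01, Q = 8, k − 1 = 2, C = 200, so
τ² = 0.03 exactly. A single effect passes through with τ² = 0 and its own
sampling standard error.

Subgroup pooling (by ecosystem or soil class) fits each cell separately
rather than entering the group as a fixed moderator — the reading most
consistent with per-panel forest plots. Subgroup cells need at least
min_k = 3 effects (the smallest k with nonzero heterogeneity df);
skipped cells are logged, and the floor is configurable. Overall pooling
has no floor.

Calibration at the default conditions (k = 50 per dataset, τ² = 0.01,
sampling variances 0.008–0.03) is measured by the acceptance script: CI
coverage ≈ 94–95 % and type-I rate of the CI-excludes-zero rule ≈ 5–6 %
over 1000 replicates. The slight undercoverage is the familiar price of
the normal quantile with estimated τ².

## Gradient synthesis (observational track)

Per-study slopes are ordinary least squares of the soil value on one
covariate over the study's sites (at least three sites with a
non-degenerate covariate). Slopes are pooled *unweighted* by an
intercept-only mixed model with a region random intercept; per-study
slope SEs are carried through the outputs for future weighted variants
but do not enter the fit, because the synthesis is of the slopes
themselves. Covariates stay in natural units (g/kg per mm, per °C, per
aridity unit); a rescaling switch exists but is off by default since
natural units are reversible.

The mixed model is fitted by REML with the residual variance profiled
out, leaving a one-dimensional search over the variance ratio
σ²_region/σ²_res on [0, 1e4]; the ratio-zero boundary is always evaluated
and wins ties. This hand-profiled form exists because the parametric
bootstrap refits the model thousands of times; the test suite verifies it
against both a brute-force two-component grid search of the matrix-form
restricted likelihood and statsmodels' MixedLM on the same data. A single
region degenerates to mean-plus-residual with σ²_region fixed at 0
(flagged on the fitted object).

The grand-slope CI is an unconditional parametric bootstrap: each of
n_boot = 1000 replicates simulates fresh region effects and residuals
from the fitted variances, refits, and the 2.5/97.5 percentiles of the
refit means form the CI (replicates are refit by a vectorized
golden-section search, ~80 iterations, with the zero-ratio boundary
compared explicitly). Replicates that fail to produce a finite mean are
discarded and counted, with a logged warning above 5 %. With both
variance components zero every replicate reproduces the fitted mean and
the CI has zero width. The seed is mandatory.

At the documented problem size (15 studies, 4 regions, 300 replicate
datasets) the bootstrap CI covers the generating slope ≈ 95–97 % of the
time and the pooled slope is unbiased to well within a tenth of its
replicate standard deviation. The mild overcoverage arises when spurious
region variance is absorbed by the random effect, widening the interval.
"Bias below 0.1·SE" is assessed against the across-replicate standard
deviation of the estimate.

## Aridity

AI = MAP/MAE (dimensionless); aridity = max(AI) − AI, the maximum taken
over the loaded dataset and recorded in the run log (it is a dataset
property, not a constant). Aridity is therefore non-negative, exactly
zero at the wettest site, and exactly anti-correlated with AI. Because
drier-as-treatment experiments and the aridity covariate both orient
"drier = larger", direction contrasts compare signs directly with no
flip for any driver pair.

## Regression suite

Five curve families in canonical forms: a + bx; a + bx + cx²; a + b ln x;
a·x^b; a·e^(bx). Linear-in-parameters families use least squares on the
transformed design; power and exponential use Levenberg–Marquardt
(maxfev 500, ftol 1e-10) started from the log-linearized fit. R² is
always 1 − SSres/SStot on the original response scale (clamped at zero
for nonlinear fits that underperform the mean). Domain violations
(x ≤ 0 for logarithmic/power, y ≤ 0 for power/exponential) and
convergence failures mark a family *inapplicable* rather than raising, so
selection proceeds over the applicable set. Model p-values are overall
F-tests against the intercept-only model — on the log-linearized form for
power and exponential — and are not multiplicity-adjusted. Selection
takes the maximum-R² family among applicable fits with p < 0.05; exact
ties go to fewer parameters, then canonical family order, and the
tie-break is recorded. Note the procedure tests several correlated
families at α = 0.05 each, so on pure noise *some* family is selected in
roughly 9–11 % of datasets; the acceptance script measures this rate
under an lnRR-like null (y ~ N(0, 0.2), x spanning a MAP-like range).

The all-subsets grid fits OLS for every non-empty subset of
{T = MAT, P = MAP, A = aridity, S = soil, E = ecosystem} — 31 models for
the full set — with categorical terms dummy-coded. Collinear designs
(common in small datasets where soil and ecosystem labels alias) use the
minimum-norm least-squares fit with rank-based degrees of freedom and are
flagged, keeping R² defined and the nested-chain monotonicity of the grid
intact. AIC uses the Gaussian form n·ln(SSres/n) + 2k with k counting
coefficients plus the error variance, so differences are invariant to
rescaling the response.

Backward stepwise elimination starts from the full term set and
repeatedly removes the term whose removal yields the lowest AIC, when
that either strictly improves the AIC or stays within 2 AIC units of the
best model seen so far — models closer than 2 units are not considered
distinct, and the smaller one is preferred (each such step is recorded).
This guarantees the final model's AIC never exceeds the full model's by
more than 2.

## Contrast and sensitivity

The direction contrast is a pure function of two direction labels:
contrasting (both significant, opposite signs), consistent (both
significant, same sign), indeterminate (anything else — the labels for
non-significant agreement are an artifact convention, kept minimal).
Magnitudes are never formally compared across the two designs; the
bootstrap distributions are not commensurable.

The reduced database keeps one uniformly random record per study
(seeded); reduction is idempotent and selection is uniform across a
study's records. The reduced mean gets a bias-corrected (BC, not BCa)
bootstrap CI: z₀ = Φ⁻¹(fraction of bootstrap means below the observed
mean), endpoints at bootstrap quantiles Φ(2z₀ ± 1.96), with the fraction
clipped away from 0 and 1 and constant input yielding a zero-width
interval. "Similar means" is operationalized solely as CI overlap between
full and reduced summaries — no extra equivalence margin is invented.

## Synthetic data

The experimental generator draws per-study-per-variable true effects
θ ~ N(μ_tv, τ²), log-normal control baselines (median 10/1/0.5 g/kg for
C/N/P; configurable), treatment means control·e^θ, group SDs cv·mean,
and observed group means from N(mean, SD/√n) — the exact sampling
distribution the lnRR variance formula assumes, so the formula is exactly
correct in-simulation. Default effect magnitudes mirror the literature
conditions the pipeline targets: water addition lowering N/P/C by about
5/9/3 % (C weakly), drought raising C/N/P by about 6/18/7 %, warming
raising N most (warming magnitudes are not well pinned by published
syntheses; modest positives were fixed once as defaults); τ² = 0.01,
cv = 0.25, group sizes 4–10, 1–3 records per study, 60 studies.

The observational generator assigns studies to regions, draws site
climate uniformly (MAP 100–1200 mm, MAT −5–20 °C, MAE 800–1800 mm so AI
spans a wide range), derives aridity dataset-wide, and sets
value = intercept + Σ β_cov·cov + u_region + ε with Gaussian region
effects and residuals. Default truth drives each nutrient through its
paired covariate (N via MAP at +4·10⁻⁴ g/kg/mm, C via MAT, P via
aridity), which keeps marginal slope recovery interpretable; 40 studies,
5–15 sites each, 6 regions. Nonpositive simulated values are redrawn
(and in the rare exhausted case clipped and counted in the truth record).

One master seed spawns independent substreams per study, so enlarging
n_studies extends a dataset without reshuffling existing studies, and
identical configs give byte-identical CSVs.

What the generators do **not** emulate: spatial autocorrelation of
climate and soils, covariance between MAT and MAP (drawn independently),
publication bias, shared controls across treatment levels, measurement
rounding, or unbalanced reporting. Passing calibration on this synthetic
structure therefore demonstrates correctness of the estimators under the
models' own assumptions, not robustness to the messiness of real
compiled literature data.

## Problem sizes and determinism

The calibration measurements use 1000 meta-analytic replicates (k = 50),
300 observational replicates (15 studies, 4 regions, 1000 bootstrap
draws each), 200-seed selection and sensitivity sweeps, and 20-study
oracle comparisons — sizes at which every Monte-Carlo band quoted above
is resolvable in well under a minute each on one core. All randomness
descends from explicit seeds through `numpy` SeedSequence spawning;
reruns with the same config are bit-identical.

## Known limitations

- Slopes are pooled unweighted; heteroscedastic slope SEs are carried but
  unused.
- The region mixed model is intercept-only; no covariate-interaction or
  spatial models.
- No publication-bias diagnostics and no meta-regression on moderators.
- The five-family selector's familywise error is inherently above the
  per-family α; it reports, and the documentation states, that behaviour
  rather than adjusting p-values.
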