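# Methods

This note records the statistical models `tmabatch` implements, the
conventions chosen where several were defensible, what the synthetic-data
generator does and does not emulate, and the limitations we know about.

## Data model and preprocessing

Biomarker measurements live in a long table keyed by
(tumor, core, marker); the TMA slide is the batch key, and every core of a
tumor sits on one slide unless explicitly flagged `cross_batch` (the
calibration design that makes the two-way model identifiable). Missing
measurements are absent rows; `NA` tokens in input files are dropped with a
logged count, while any other non-numeric token is a hard parse error —
silent coercion of malformed values has no place in a measurement pipeline.
Files are comma-separated UTF-8 with `.` decimals; the writer emits
shortest-round-trip float strings so write→read is bit-exact.

Preprocessing follows the field's convention for TMA scores: right-skewed
markers may be natural-log transformed (only for strictly positive values,
or with a declared offset), cores are summarized as the per-tumor mean, and
markers may be scaled to overall mean 0, SD 1. The z-scale uses the sample
(n−1) denominator. Aggregation-then-scaling is the default order; the
reverse is available as a configuration option because the order is a
genuine free choice (it changes nothing about batch structure, only the
unit of "1 SD").

## Diagnosis

ICCs come from REML mixed models: a one-way random intercept for the batch
share, and, on cross-batch duplicate cores, a crossed two-way model
(batch + tumor random effects, fit as variance components on a single
grouping) that separates slide variance, tumor variance (intratumoral
heterogeneity at the core level), and residual error. Negative variance
estimates are truncated at zero; a boundary fit reports ICC 0 with its
convergence flag. On balanced designs the REML one-way ICC agrees with the
ANOVA method-of-moments decomposition, which the test suite uses as an
independent oracle.

Confidence intervals are percentile intervals (2.5/97.5) from a parametric
bootstrap: simulate from the fitted variance components on the observed
design, refit, repeat (default 500 replicates; every stochastic routine
takes an explicit seed). If more than 20% of refits fail the interval is
flagged unreliable. The permutation null for the ICC shuffles tumor-to-slide
assignments — the tumor is the permutation unit, because cores of a tumor
share a slide — and reports the 97.5th percentile of the null ICC: an
observed ICC above it indicates batch structure beyond chance.

The effect-modification test asks whether tumors with particular grade,
stage, or diagnosis era are differentially affected by high-reading slides:
within-slide z-scores are regressed on the clinical feature, the slide mean,
and their interaction, with a slide random intercept; the interaction
coefficient's p-value uses the normal approximation on β/SE (no
degrees-of-freedom correction — the reference models in this literature
report none, and slide counts are moderate).

PCA embeds tumor-level marker profiles after column standardization;
complete-case handling is the default, marker-mean imputation optional.

## The seven corrections

All corrections preserve the input row keys, return per-batch effect
estimates alongside corrected values, and express location effects relative
to the observation-weighted pooled mean (a reference-batch convention would
only shift all values by a constant). Methods 2–4 and 6 preserve
within-batch rank order.

1. **Uncorrected** — baseline.
2. **Simple means** — subtract batch mean − overall mean. Post-correction
   batch means are exactly equal.
3. **Standardized means** — batch coefficients from OLS of the biomarker on
   batch indicators plus retained covariates (Gleason grade group and
   pathological stage categorical, diagnosis year linear). Covariate-
   explained between-batch differences are deliberately retained; with an
   empty covariate list the method reduces exactly to simple means.
   Rank-deficient designs (a covariate level aliased with a batch) fall
   back to the pseudoinverse with a warning.
4. **IPW means** — stabilized weights P(batch)/P(batch|C) from a
   multinomial logistic model (unpenalized, tolerance 1e−10), truncated at
   the 2.5th/97.5th percentiles of the weight distribution (configurable;
   (0,100) disables truncation), then weighted batch means in the
   pseudopopulation. The weighted marginal model is weighted least squares.
   Degenerate membership probabilities raise an error advising covariate
   coarsening.
5. **Quantile regression** — batch-specific lower/upper quartiles from
   quantile regressions at τ = 0.25 and 0.75 (statsmodels' iteratively
   reweighted least squares; the interior-point solver used elsewhere in
   the literature targets the same estimand), unadjusted and
   covariate-adjusted. Each value is offset by its batch's unadjusted lower
   quartile, rescaled by overall IQR / adjusted batch IQR, and re-anchored
   at the overall lower quartile, retaining the adjusted–unadjusted
   lower-quartile difference. Adjusted batch quantiles are predictions at a
   fixed covariate profile (continuous covariates at their mean, categorical
   at the mode). A minimum batch size (default 10) guards quartile
   stability; an adjusted IQR at or below ~0 (relative floor 1e−6 of the
   overall IQR) is a hard error naming the batch.
6. **Quantile normalization** — each value maps to its within-batch
   quantile position p = (rank−1)/(n−1) (ties averaged; a single-observation
   batch maps to the median with a warning) and is replaced by the mean
   across batches of the batch quantile functions at p (linear
   interpolation for unequal batch sizes — the dominant array-normalization
   convention). All batches share one post-correction distribution.
7. **ComBat** — parametric empirical Bayes across a marker panel:
   per-marker standardization with covariate adjustment, per-batch
   location/scale estimates, normal/inverse-gamma priors with
   moment-matched hyperparameters, and the standard fixed-point iteration
   for the posteriors (relative tolerance 1e−6). Markers are partitioned by
   the exact set of slides they were measured on and each group is adjusted
   jointly (a marker absent from a whole slide cannot share a run); at
   least two markers per group are required, since shrinkage pools across
   markers. Estimation uses complete samples; the fitted correction is
   applied to every row, so keys are preserved. A batch with a single
   sample takes the prior scale with a warning. The implementation agrees
   with Bioconductor sva's `ComBat` to ~1e−6 on shared fixtures (asserted
   in the test suite via `Rscript`).

Two behaviors of these methods are worth knowing before interpreting
"residual" batch variance. First, methods 3 and 4 retain real
covariate-driven between-batch differences by design, so on data where the
biomarker tracks a covariate that is imbalanced across slides, their
post-correction ICC is not zero — that is the point of the methods, not a
failure. Second, if a retained covariate is nearly collinear with the batch
indicator (e.g., diagnosis year when each slide covers a narrow, disjoint
era), the covariate coefficient is estimated with large variance and the
"retained" component is mostly noise; the methods cannot separate batch
from covariate in that design, and neither can any other.

EB shrinkage also has a visible signature: when the panel is small or batch
artifacts are nearly identical across markers, across-marker heterogeneity
looks like noise and ComBat removes only the common component, leaving
per-marker residuals (~10% residual variance ratio is typical); with
marker-specific artifacts and a panel of ~20 markers the correction is
nearly complete. This matches the reference implementation exactly.

## Outcome models

- **Linear trend**: biomarker (in SD units) per one Gleason grade-group
  increase (groups ordered 1–5), OLS with normality-based CIs.
- **Cox per SD**: univariable proportional-hazards fit (lifelines), Efron
  tie handling, HR per 1 SD. CIs are estimate ± 1.96·SE on the log scale.
- **Cox quartiles**: Q4 vs Q1 hazard ratio; quartile cuts on the pooled
  analysis population after any correction; ties that collapse a quartile
  trigger a tie-broken re-cut with a warning.
- **Stratified Cox (approach 9)**: batch-specific baseline hazards, one
  pooled coefficient. The biomarker is centered within batch before the
  fit — a no-op for the partial likelihood that makes the result invariant
  (to ~1e−12; the last ulp of the within-batch mean may differ) under any
  per-batch additive shift of the input. Batches with zero events are
  dropped with a warning; they contribute no information either way.
- **Per-batch pooling (approach 8)**: the chosen model fit separately per
  batch, pooled with fixed-effect inverse-variance weights
  (SE = 1/√Σw). By default each batch standardizes by its own SD — each
  batch analyzed as its own study — which absorbs per-batch scale
  artifacts; `per_batch_sd=False` gives per-unit coefficients directly
  comparable to the stratified fit. Failed or event-free batch fits are
  skipped with a warning.

A finding from validating these estimators worth recording: fixed-effect
inverse-variance pooling of per-batch Cox fits carries the same asymptotic
information as the stratified partial likelihood, so their interval widths
essentially coincide when batches have ample events (we verified the
stratified SE against R's `survival::coxph` and the pooled SE against
per-batch `coxph` fits; both match). A width penalty for pooling appears
only when batches carry a handful of events each and per-batch fits
destabilize — the regime of real TMA series with rare lethal outcomes — and
even there it is a few percent on average, not dramatic. Interval-width
comparisons between approaches 8 and 9 are only meaningful on a common
coefficient scale; per-batch standardization silently changes the unit
(within-batch SD vs overall SD) and can masquerade as an efficiency
difference.

## Plasmode simulation engine

The engine fixes the biomarker–outcome association while preserving an
empirical study's covariate, batch, and censoring structure.

- **Baseline hazard**: log cumulative hazard as a restricted cubic spline
  in log time. "Three knots" is read as the total: boundary knots at the
  extreme uncensored log event times, one interior knot at their median
  (configurable). With no interior knot the model is Weibull; with unit
  slope, exponential — both serve as closed-form oracles, and the fitted
  no-interior-knot model reproduces lifelines' Weibull MLE to ~1e−3.
- **Fitting**: full maximum likelihood (Nelder–Mead polish then BFGS),
  exponential-law initialization, a hard penalty on non-monotone cumulative
  hazards at event times; a fit that remains non-monotone over the data
  range is refit without interior knots, with a warning.
- **Simulation**: per subject, U ~ Uniform(0,1); S(t) = U is inverted on
  the log-time scale by bracketed Brent root-finding (tolerance 1e−12; the
  spline is linear beyond its boundary knots, so the bracket always
  expands to a solution). Confounder–outcome coefficients are carried over
  unchanged; only the biomarker coefficient is replaced by the chosen true
  log HR. Each subject's observed follow-up time acts as an administrative
  censoring bound (re-simulating censoring is out of scope; this preserves
  the empirical follow-up structure exactly).
- **Batch-effect injection**: means-only adds δ_j; means-and-variance
  rescales around the batch mean by s_j and then adds δ_j; the modified
  variant scales both δ_j and (s_j − 1) per tumor by
  1 + κ·(Gleason score − mean), κ = 0.25 by default, linking the artifact
  to grade. Default synthetic artifacts: shifts N(0, 0.7²) in biomarker-SD
  units, scales log-evenly spaced and geometrically symmetric around 1 with
  a variance ratio of 9 between the most extreme slides — magnitudes chosen
  to match what strongly affected markers show in practice.
- **Scoring**: per (scenario, method), 200 replicates by default; replicate
  seeds derive from seed + replicate index, and deliberately ignore the
  scenario index, so scenarios sharing a scenario seed reuse identical
  simulated outcomes and bias contrasts between batch-effect kinds are
  paired. Reported: geometric-mean HR, mean log HR, empirical 95% range,
  log-scale bias, CI coverage, mean CI width, failure count (a cell with
  >10% failed replicates is flagged). Cox fits in the grid are per unit of
  the generation-scale standardized biomarker. ComBat is excluded from the
  grid: it requires a multi-marker panel and the grid simulates one marker.

Two estimand subtleties the engine makes visible, both worth keeping in
mind when reading simulation tables. First, a univariable Cox fit on data
whose hazard also depends on omitted prognostic covariates is attenuated by
non-collapsibility even with a perfectly measured, independent biomarker;
with Gleason/stage effects of realistic strength this is ≈ −0.12 on the log
HR at a true HR of 3, and it vanishes at the null. It is not a batch
phenomenon — it is identical across batch-effect scenarios — which is why
batch-effect bias should be read against the no-batch-effect baseline of
the same method (the paired replicate seeds make that contrast tight).
Second, when slide-level artifacts are fixed across replicates and the
covariate mix differs across slides, the chance correlation between the
drawn shifts and slide-level event rates acts as genuine confounding by
batch and offsets even null associations; the null-calibration check
therefore uses a composition-balanced covariate table, where that term
re-randomizes across replicates and averages away.

## Synthetic-data generator

`generate_study` draws, per batch: a tumor count (uniform 47–158 by
default), Gleason grade-group and stage compositions (under
`observed_like` imbalance the high-grade fraction spans 11–33% across
batches and per-batch median diagnosis years span 14 years, each slide
accruing cases over ±5 years so year is informative about batch without
being collinear with it), then per tumor: a biomarker mean (covariate
effects + tumor random effect, SD 1), core values (mean + noise, SD 0.5,
3 cores), a per-batch affine artifact (shift, scale — one shared pattern or
independent draws per marker), and an exponential event time with log
hazard = confounder effects (0.5 per grade group, 0.3 per stage step —
realistic prognostic strength, producing per-batch lethal-event rates of
roughly 2–16 per 1000 person-years) + true log HR × standardized biomarker,
administratively censored at 25 years. Drawn batch shifts are standardized
to exact mean 0 / nominal SD: with only ~14 batches the realized spread of
raw draws is far from nominal, and pinning the first two moments makes
generative ICCs exact so parameter-recovery tests have a well-defined
truth. `generate_crossbatch_subset` emits the calibration design — by
default 10 tumors whose 53 cores split across ≥2 slides — from the
three-component generative model (defaults 0.30/0.37/0.33).

What the generator does **not** emulate: staining chemistry and image
scoring (batch artifacts enter as affine location/scale maps, not as
censoring at antibody saturation or detection floors), correlated artifact
patterns across markers stained on the same section, non-proportional
hazards, competing risks, and informative censoring. Tests passing on this
generator therefore demonstrate that the estimators recover the truth under
the stated generative model — additive/multiplicative batch artifacts on
top of a linear covariate structure — not that any particular real marker
behaves this way.

## Problem sizes and numerical choices

Test-suite simulations run at the study scale the methods target (14
batches × ~100 tumors) with replicate counts chosen for stable Monte-Carlo
contrasts on one CPU: 200 replicates for null calibration, 50 for the
method-ranking grid, 100–200 bootstrap replicates where intervals are
asserted. Root-finding tolerance is 1e−12 in log time; ComBat's EB
iteration converges at 1e−6 relative change; the IPW multinomial model uses
tolerance 1e−10 so that exactly balanced designs reproduce simple means to
1e−6. REML boundary fits are reported, not hidden: `converged` and
`ci_reliable` flags travel with every ICC.

## Known limitations

- The two-way crossed model on the 10-tumor calibration subset has wide
  sampling variability by construction; only bootstrap intervals, not point
  estimates, are meaningful at that size.
- Quantile-regression correction needs ~10+ observations per batch for
  stable quartiles and still leaves residual batch variance when covariate
  effects differ across quantiles — consistent with how this approach is
  characterized in the literature.
- The IPW multinomial model degenerates if a covariate separates batches
  perfectly; the error message suggests coarsening, which is the practical
  remedy.
- Fixed-effect pooling assumes a common biomarker effect across batches;
  random-effects pooling is out of scope.
- ComBat's nonparametric prior mode is out of scope; the parametric mode is
  the one in near-universal use.
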