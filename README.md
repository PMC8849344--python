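# tmabatch

Batch-effect diagnosis, mitigation, and validation for protein-biomarker
studies on tissue microarrays (TMAs).

Studies that quantify tumor biomarkers on more than one TMA slide face a
measurement problem: even with fully standardized staining and scoring, some
slides read systematically too high or too low, and some spread their values
more widely than others. Each TMA slide is a measurement **batch**, and
between-batch differences in location and scale — batch effects — attenuate
or distort the biomarker–outcome associations the study exists to estimate.
`tmabatch` provides the full analytical workflow for this situation:

1. **Diagnose** — quantify the between-batch share of biomarker variance
   with intraclass correlation coefficients (ICCs) from random-effects
   models, with parametric-bootstrap confidence intervals and a permutation
   null; separate batch variance from intratumoral heterogeneity when some
   tumors contribute cores to several slides; test whether batch shifts
   scale with clinical features; visualize batch clustering in PCA space.
2. **Correct** — seven value-level approaches, from uncorrected through
   simple batch-mean centering, covariate-standardized means,
   inverse-probability-weighted means, quantile-regression location–scale
   correction, quantile normalization, and empirical-Bayes (ComBat-style)
   adjustment across a marker panel.
3. **Model outcomes batch-aware** — ordinal Gleason trend models and Cox
   proportional-hazards models (per-SD, extreme-quartile, batch-stratified,
   and per-batch fits pooled by inverse variance).
4. **Validate** — a plasmode-style simulation engine that fits a flexible
   parametric survival model (restricted-cubic-spline log cumulative
   baseline hazard) to a covariate table, re-simulates event times at an
   investigator-fixed biomarker hazard ratio, injects batch effects of
   known form, and scores every correction method against the known truth.

A synthetic-data module generates full multi-batch studies (14 slides,
47–158 tumors each, ~3 cores per tumor, imbalanced clinical covariates,
time-to-event outcomes) so the entire pipeline is testable without access
to restricted cohort data.

## The models

**Variance decomposition.** For biomarker level $Y_{ij}$ of tumor $i$ on
slide $j$, the one-way random-effects model
$Y_{ij} = \beta_0 + r_j + e_{ij}$, $r_j \sim N(0,\sigma_r^2)$,
$e_{ij} \sim N(0,\sigma_e^2)$, fit by REML, gives the between-batch share

$$\mathrm{ICC} = \frac{\sigma_r^2}{\sigma_r^2 + \sigma_e^2}.$$

When cores of the same tumor sit on different slides, the crossed two-way
model $Y_{ijk} = \beta_0 + r_j + s_i + e_{ijk}$ adds tumor effects $s_i$ and
separates slide variance from intratumoral heterogeneity:
$\mathrm{ICC} = \sigma_r^2 / (\sigma_r^2 + \sigma_s^2 + \sigma_e^2)$.

**Correction.** Mean-based methods estimate per-batch location effects
$\hat\beta_j$ (raw means; covariate-adjusted means via
$Y_{ij} = \beta_0 + \beta_j B_j + \gamma_1 C_1 + \dots + \gamma_m C_m + e_{ij}$;
or means in a pseudopopulation weighted by stabilized weights
$P(B_j)/P(B_j \mid C)$) and subtract the centered $\hat\beta_j$.
Scale-aware methods additionally equalize spread: quantile regression maps
each batch's quartiles onto the overall quartiles,

$$y^*_{ij} = (y_{ij} - \hat y_j^{\,\tau=.25})
\frac{\bar y^{\,\tau=.75} - \bar y^{\,\tau=.25}}
     {\hat y_j^{\,\tau=.75,*} - \hat y_j^{\,\tau=.25,*}}
 + \bar y^{\,\tau=.25} - \hat y_j^{\,\tau=.25,*} + \hat y_j^{\,\tau=.25},$$

quantile normalization replaces within-batch ranks by cross-batch mean
quantiles, and ComBat shrinks per-batch location/scale parameters across
markers with parametric empirical-Bayes priors (normal / inverse-gamma).

**Validation.** The plasmode engine fits
$\log H(t \mid x) = s(\log t;\gamma) + x^\top\beta$ with $s$ a restricted
cubic spline (three knots), replaces the biomarker coefficient with a chosen
$\log \mathrm{HR}$, draws $U \sim \mathrm{Unif}(0,1)$ per subject, and
inverts $S(t)=U$ on the log-time scale, keeping observed covariates,
confounder–outcome coefficients, and censoring structure fixed.

## Worked example

```python
import numpy as np
from tmabatch import StudyDesign, generate_study
from tmabatch.datamodel import PreprocessSpec, preprocess
from tmabatch.diagnose import icc_one_way, icc_bootstrap_ci, icc_permutation_null
from tmabatch.correct import correct_quantile_norm
from tmabatch.outcomes import cox_per_sd, cox_stratified

design = StudyDesign(n_batches=14, tumors_per_batch=(47, 158), n_markers=2,
                     batch_shift_sd=0.7, true_log_hr=np.log(2), seed=7)
biomarkers, covariates, truth = generate_study(design)
per_tumor = preprocess(biomarkers, PreprocessSpec(aggregate_cores="mean"))

icc = icc_bootstrap_ci(icc_one_way(per_tumor, "marker1"), n_rep=200, seed=1)
null975 = icc_permutation_null(per_tumor, "marker1", n_perm=200, seed=1)
corrected = correct_quantile_norm(per_tumor, "marker1")
```

Output (biomarker generated with additive batch shifts of SD 0.7 and a true
hazard ratio of 2 per SD):

```
between-TMA ICC: 31.5% (95% CI 14.7%-47.2%; permutation null 97.5th pct 0.7%)
ICC after quantile normalization: 0.00%
HR per SD, uncorrected: 1.73 (95% CI 1.51-1.99), n=1585, events=220
HR per SD, quantile-normalized: 1.82 (95% CI 1.58-2.08), n=1585, events=220
HR per SD, batch-stratified: 2.08 (95% CI 1.77-2.46), n=1585, events=220
```

Reading: 31.5% of the biomarker's variance is attributable to slides — far
above the ~0.7% that tumor-to-slide assignment chance alone produces — so
batch effects must be addressed. Quantile normalization removes the
between-slide variance entirely; the uncorrected per-SD hazard ratio (1.73)
is attenuated toward the null relative to the corrected (1.82) and
batch-stratified (2.08) analyses.

The same pipeline is available from the shell:

```bash
tmabatch simulate-data --seed 7 --out study/
tmabatch run --biomarkers study/biomarkers.csv \
             --covariates-file study/covariates.csv --method 6 --out results/
```

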