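# Methods

`lipidcap` re-implements, as a tested library, a targeted plasma-lipidomics
biomarker workflow for community-acquired pneumonia (CAP) versus
infection-associated COPD exacerbation and matched controls. The original
cohort data are not publicly deposited, so the package ships a synthetic
cohort generator whose defaults encode the study design; every analysis
stage is exercised end to end against that generator and its ground-truth
sidecar.

## Data model

A `Dataset` couples a samples × analytes concentration matrix (µM) with a
missingness mask and per-sample metadata (subject, group ∈ {CAP, COPD,
CTRL}, timepoint ∈ {d1, d2, d4, f1, f2, single}, age, sex, CRP, PCT, acid
sphingomyelinase activity, corticosteroid use). The default panel holds 145
analytes — 76 phosphatidylcholines (38 diacyl `aa` + 38 acyl-alkyl `ae`),
14 lysophosphatidylcholines, 15 sphingomyelins (5 hydroxylated) and 40
acylcarnitines — with an optional 4-ceramide extension treated as ordinary
analytes of class CER. Names follow the `Cx:y` convention (total side-chain
carbons : total double bonds) and are parsed into class/bond/moiety
structure; panel LODs are configuration data (`panel.yaml`), not method.

A cell is *missing* when unmeasured or below the analyte LOD. Below-LOD raw
values are retained in files (the mask is reconstructed from the LOD rule on
read, so round trips are exact) but are treated as missing for analysis and
replaced by imputation.

## Synthetic cohort generator

Concentrations are log-normal. For analyte *a* in a sample of subject *s*
(group *g*, timepoint *t*):

    log c = log b_a + u_{s,a} + s_s · r_class(t) · (1 + j_a) · log m_{a,g} + ε

- `b_a` — per-analyte baseline, drawn once per cohort around a class-typical
  level (PC aa 30 µM, PC ae 4, lysoPC 12, SM 10, SM(OH) 1.5, AC 0.12, CER
  0.6; between-analyte log-SD 1.0). Plasma metabolite concentrations are
  strictly positive and right-skewed, which the printed group medians and
  ranges are consistent with; hence the log-normal family.
- `m_{a,g}` — class-level disease multiplier with per-analyte overrides.
  Defaults mirror the study's effect structure: PC strongest down in CAP
  (0.45×), then lysoPC (0.55×), SM (0.70×); acylcarnitines flat except the
  short-chain C5 (1.6× up); PC ae C36:0 up; three SM up in COPD only;
  ceramides C16:0/C18:0/C24:1 up in CAP. COPD multipliers are milder
  (PC 0.75×, lysoPC 0.8×).
- `r_class(t)` — fraction of the admission effect remaining at each
  timepoint (non-increasing from 1). LysoPC recovers fastest
  (1, .8, .55, .3, .05), PC slowest (1, .9, .75, .55, .35): recovery speed is
  a class property, which is what the resolution screen is meant to detect.
- `s_s` — a latent per-subject inflammation scalar (log-normal, median 1,
  log-SD 0.25) that multiplies the lipid log-effects *and* the clinical
  marker log-effects. This single shared factor produces the predominantly
  negative lipid–CRP/PCT correlations without hard-coding any correlation
  target.
- `u_{s,a}` — subject × analyte random intercepts (log-SD 0.35), giving
  repeated-measures correlation along the CAP time course; `j_a` — ±15%
  per-analyte effect jitter; ε — measurement noise (log-SD 0.15).

Cohort structure defaults: 29 CAP subjects × 5 timepoints with exactly one
subject lost to follow-up after d4, 13 COPD and 33 control subjects sampled
once; ages ~N(60, 14) clipped to 24–90; 40% female; corticosteroid
probabilities 22%/62%/3.3% (CAP/COPD/CTRL).

Clinical markers are log-normal with admission medians CRP 102/14/3.1 mg/l,
PCT 0.23/0.09/0.02 ng/l (draws floored at the assay reporting limits 3.1
and 0.02, reproducing the pile-up of control values there) and ASM activity
280/175/100 arbitrary units, i.e. the 2.8- and 1.75-fold admission
elevations. The CAP marker effect decays by (1, .75, .55, .25, .05) over the
time course. The ASM log-SD (0.45) was set analytically so the configured
2.8-fold separation implies a true ROC area near the reported 0.94.

**LODs.** Per-analyte LODs are placed at a quantile of a log-normal fit to
the simulated control marginal. Well-detected analytes use quantile 1e-4 —
kit LODs sit far below normal plasma levels for abundant phospholipids, and
an LOD near the control range would censor the depressed CAP samples so
heavily that whole classes fail QC, which is not what the assay does. A
fixed set of 34 poorly quantified analytes (30 acylcarnitines and 4 rare
phospholipids) uses quantile 0.85 instead, so the detection-fraction filter
removes them: under defaults 111 of 145 analytes pass, matching the study's
detection behaviour. A parametric (rather than empirical) quantile keeps
censoring monotone in the quantile and allows LODs below the control
minimum.

A `TruthSidecar` records the expected multiplicative effect per analyte ×
group × timepoint, per-sample expected marker medians, baselines and the
latent inflammation scalars, enabling parameter-recovery tests.

**What the generator does not emulate:** assay batch/plate effects,
compositional or analytical correlations between analytes beyond the shared
inflammation factor, non-log-normal tails, informative dropout, diet/fasting
effects, and any mechanistic lipid metabolism. Passing tests therefore show
that the statistical machinery recovers known structure of this form — not
that the biological effect sizes are real.

## Preprocessing

*QC filter*: keep analytes with a measured value above LOD in at least 75%
of all samples (inclusive threshold, pooled over groups and timepoints).
*Imputation*: per analyte, ordinary least squares of the observed
concentrations on age, sex, group indicators and timepoint indicators
(controls/COPD at the reference timepoint level, so time effects are
estimated from the CAP course only); missing cells take the model
prediction, floored at half the analyte LOD because predictions can be
negative while concentrations cannot. One pooled model per analyte —
"disease state and timepoint" as predictors implies a single fit across
groups. Rank-deficient designs (e.g. single-group toy data) are resolved by
minimum-norm least squares with a warning. Imputation never touches
observed cells and errors if an analyte has fewer than p + 2 observations.

## Metabolic indicators

47 defaults: 11 class sums, 11 class ratios, 25 lipid-pair ratios,
including total lysoPC, total SM, total SM/total PC,
lysoPC a C16:0/C16:1, lysoPC a C20:4/C20:3 and dicarboxyl-AC/total AC.
Definitions live in `data/indicators.yaml` (explicit name lists or panel
selectors by class/bond/moiety/double-bond count) so the exact original set
can be dropped in if obtained. Sums are per-sample (µM); ratios are
dimensionless; a zero denominator flags that sample undefined for that
indicator, and an indicator that loses all members to the QC filter is
skipped with a warning. Scale covariance (sums scale with the data, ratios
do not) is property-tested.

## Differential abundance

Fold change = ratio of case to control medians. Mann–Whitney U (two-sided
asymptotic, average ranks, tie and continuity corrections; the U statistic
is returned so that U/(n₁n₂) equals the empirical ROC area) and
Kruskal–Wallis H (tie-corrected, χ² approximation) for the CAP time course.
Benjamini–Hochberg step-up at FDR 0.05, applied separately to the analyte
and indicator families of each contrast (the two families are annotated
independently in the source analyses). Completely tied inputs yield the
degenerate p = 1. The continuity correction keeps the asymptotic p within
0.02 of exact permutation enumeration at n = 5 per group.

## Biomarker ROC analysis

Per feature: a univariate logistic scorer (standardization and model fitted
on training folds only; C = 1e6, i.e. effectively unregularized) evaluated
by stratified 5-fold cross-validation repeated 25 times. Mean AUC over the
125 fold AUCs; 95% CI as their 2.5/97.5 percentiles — distribution-free and
the natural interval for repeated CV. Biomarker call: mean AUC ≥ 0.80
("excellent classification"), asymptotic Mann–Whitney p < 0.05, and CI not
crossing AUC = 0.50. Direction (whether high or low values indicate
disease) is recorded from the raw feature's full-data ROC orientation,
since the trained scorer orients itself.

Sample-size sensitivity: the minority group is oversampled to the majority
size by random draws with replacement (all originals kept, duplicates
tagged). Oversampling happens before CV, replicating the referenced
procedure; duplicates can then span folds and inflate accuracy, which is
why duplicates are tagged and the analysis is reported alongside — not in
place of — the original. The corticosteroid check fits a logistic model on
the standardized feature plus the treatment indicator and reports the Wald
p for the feature; perfect aliasing and separation are detected and flagged
rather than yielding a spurious p.

## Resolution screen (LFS / NDF)

For each feature the five CAP-timepoint medians are divided by the control
median and regressed on ordinal time 1..5 (follow-up visits occur at
variable per-patient times, so calendar days are not used; the x-axis is
configurable). LFS is the OLS slope. NDF is the sum of absolute *vertical*
residuals divided by the range of the five ratios, then by 5; vertical
rather than perpendicular distance because the axes carry different units.
A constant series has NDF 0 by convention (it fits its own line perfectly).
Features are ranked by |LFS| · (1 − min(NDF, 1)); features whose admission
ratio sits on the wrong side of 1 relative to the slope (moving away from
control levels) are flagged and sorted below normalizing ones. The (LFS,
1 − NDF) coordinates are exported so users can apply their own cut, as the
original selection was visual.

## Ordination and correlations

Features are standardized to zero mean and unit *population* variance
(divisor n, matching the PCA convention; constant columns dropped with a
warning). PCA centroids are per-(group, timepoint) mean score vectors;
loadings are exported. The between-group "reprogramming distance" is the
Euclidean distance between group mean vectors in the full standardized
feature space divided by √(number of features): a 2-D PCA projection would
confound comparisons between feature subsets of different dimensionality,
and the √p normalization makes the whole panel, single classes and the
indicator set commensurable. Pearson r (with two-sided p) of each feature
against CRP and PCT is computed over the pooled CAP time course only.

## Pipeline

`run_all` executes simulate → qc → impute → indicators → diff → roc → lfs →
ordination → correlate, writing plain CSV artifacts and a manifest with
SHA-256 hashes per stage. One master seed fans out to per-stage child seeds
via `numpy.random.SeedSequence.spawn`, so identical config + seed gives
byte-identical outputs and each stage is independently reproducible.
Thresholds (detection fraction 0.75, FDR 0.05, AUC 0.80, α 0.05, k = 5,
25 repeats) are `RunConfig` fields validated before any stage runs.

## Problem sizes and numerical choices

Tests and the acceptance script run at the study's group sizes (29/13/33);
Monte-Carlo checks use 50 generator seeds for qualitative orderings, 500
features for null calibration, 1,000 random vectors for the BH oracle and
full enumeration (252 splits) for the permutation check. The determinism
check uses 2 CV repeats — hash equality does not depend on the repeat
count. Tolerances: OLS against the normal equations at 1e-10; ROC/U
identity at 1e-12; imputation exactness on noiseless linear data at 1e-8;
asymptotic-vs-exact Mann–Whitney at 0.05.

## Known limitations

The indicator set is a reconstruction (the original 47 definitions are not
public); per-analyte baselines and LODs are order-of-magnitude plausible
only; the imputation model is a single OLS pass without uncertainty
propagation; the covariate-adjusted test reports no penalized fallback
p-value under separation; and none of the paper's real-cohort headline
numbers (46 CAP biomarkers, best AUC 0.97, ...) can be reproduced without
the undeposited clinical data — the package reproduces the *procedures* and
their behaviour on cohorts with known structure.
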