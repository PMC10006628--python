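# Methods

This note records the models, conventions and design choices behind
somastrat, in the order data flow through the pipeline.

## Normalization and calibration

All five corrections are multiplicative and built on one primitive: the
median of ratios of a reference to the measured values.

* **Hybridization control normalization.** Reference per control = median
  RFU of that control within the plate. Sample factor = median over the
  (default 12) controls of reference/measured; every RFU in the sample,
  controls included, is multiplied by it. This equates each sample's
  median control ratio to 1 against the defining (pre-scaling) reference.
* **Intraplate median signal normalization.** Calibrator samples only.
  Local reference per SOMAmer = median over the plate's calibrators.
  One factor per (calibrator × dilution set) = median over that set's
  analyte SOMAmers of reference/measured. Three dilution sets give three
  factors per sample.
* **Global calibrator reference.** Per-SOMAmer median over all calibrator
  samples across plates, computed after the two steps above.
* **Plate scaling.** Per plate, the median over SOMAmers of
  (global reference / local calibrator median) is applied to every
  measurement on the plate.
* **Calibration.** Per (plate × SOMAmer), the factor
  (global reference / local calibrator median) recomputed after plate
  scaling is applied to all of that SOMAmer's measurements on the plate;
  afterwards each plate's calibrator medians equal the global reference
  exactly.
* **Median normalization to a reference.** Study, QC and buffer samples
  get one factor per dilution set, the median of reference/measured over
  that set's SOMAmers. The assay's external population reference does not
  exist in a self-contained pipeline; the calibrator reference doubles as
  the normalization reference, which in a pooled-plasma design carries the
  population-average profile with only ~1–2% estimation noise. An external
  reference can be substituted by passing any `GlobalReference`.

Conventions: even-count medians are the midpoint of the two central order
statistics (numpy); hybridization controls are excluded from all
analyte-level medians and from aggregation; every step operates on a copy.
QC verdict: hybridization, intraplate and plate factors must lie in
[0.4, 2.5]; ≥85% of the QC samples' per-SOMAmer ratios to the
normalization reference (taken after the full chain) must lie in
[0.84, 1.19]. Median-normalization factors are recorded but not banded —
buffer (background-only) samples make their magnitudes uninformative.

On noise-free data the chain is exactly idempotent in the hybridization,
intraplate, plate and calibration factors; the median-normalization factor
is only approximately idempotent because its reference is recomputed.

## Preprocessing

Flagged reagents are dropped first; proteins measured by several SOMAmers
are averaged per patient **on the RFU scale**, then log2-transformed (the
aggregation-before-log order is a convention; the two orders differ by
Jensen-gap amounts that are small at these noise levels). Standardization
is derivation-anchored: per-protein mean and sample SD (denominator n−1;
`ddof` configurable) estimated on the derivation cohort and applied frozen
to any other cohort or single patient. Constant columns are an error, not
a silent drop.

Missing clinical values (27 variables, sparse missingness) are completed
by iterative-PCA single imputation: columns are centered and scaled,
missing cells start at the column mean, and the algorithm alternates a
truncated rank-r SVD reconstruction with re-imputation of the missing
cells until the imputed values move by <1e-6 (cap 200 iterations, warning
on non-convergence). Default rank r = 2 — enough to capture the dominant
group-plus-severity structure of the simulated tables while staying far
from interpolating noise. Observed cells are never altered; binary
variables ride along as 0/1 columns and are not rounded, since they enter
downstream models as numeric covariates.

## Competing risks

Cause 1 is HF hospitalization, cause 2 all-cause death, 0 censoring.

* **Aalen–Johansen CIF**: F̂₁(t) = Σ_{t_j ≤ t} Ŝ(t_j−) d₁ⱼ/nⱼ with Ŝ the
  all-cause Kaplan–Meier survivor. Without censoring,
  F̂₁ + F̂₂ + Ŝ = 1 to machine precision.
* **Fine–Gray regression**: the IPCW-weighted partial likelihood keeps
  cause-2 failures in later risk sets with weight
  w_i(t) = Ĝ(t−)/Ĝ(T_i−), Ĝ the Kaplan–Meier estimator of the censoring
  distribution (left-continuous evaluation). Newton–Raphson from β = 0
  with step-halving (monotone ascent), Breslow tie handling, convergence
  at relative log-likelihood change < 1e-9, cap 100 iterations;
  |β| > 20 is treated as separation. Standard errors are model-based
  (inverse observed information) — deliberately not the robust sandwich
  variance, so confidence intervals can be narrower than those of
  sandwich-based software; the point estimate agrees with the reference
  R implementation to ~1e-7 on shared fixtures. CI level fixed at 95%.
* The genome-wide screen fits one single-covariate model per protein.
  Because the risk-set weights depend only on the outcomes, all fits share
  them and are solved by one vectorized Newton iteration (steps clipped to
  ±1; no per-protein step-halving is needed for the concave 1-D
  likelihoods); the scalar estimator is the reference path and the two are
  tested to agree to 1e-6. Proteins whose fit fails stay in the Bonferroni
  denominator m but cannot be selected.

## Stratification

k-means (Lloyd, greedy k-means++ seeding, 25 restarts, fixed seed) on the
selected proteins in standardized space; k ∈ {2..6} chosen by the overall
average silhouette width with Euclidean distance, ties to the smaller k.
Silhouette uses s(i) = (b−a)/max(a,b); points in singleton groups
contribute 0 (convention). Validation patients are assigned to the nearest
centroid; exact ties go to the lowest group index (probability-zero but
fixed for determinism). When outcomes are supplied, groups are renumbered
by ascending crude cause-1 incidence so that the highest label is the
high-risk group. Group comparisons use Welch's t (Satterthwaite df) for
continuous and chi-square without continuity correction (configurable) for
binary variables, at raw p < 0.05. The sensitivity analysis re-clusters
without chosen marker proteins at the same k, maps new groups to old by
the overlap-maximizing bijection (exhaustive over permutations), and
counts label changes in both cohorts.

## Enrichment

One-sided hypergeometric upper tail per term,
P(X ≥ overlap), X ~ Hypergeom(|universe|, term size, |selected|), raw
p-values by default with an optional Bonferroni flag. Term sets come from
a two-column TSV; no ontology graph is modeled.

## Synthetic data generator

The generator defines the study conditions; its defaults mirror the
derivation cohort's shape: 254 patients; 5284 SOMAmer reagents of which
414 are flagged for removal and 197 proteins are measured by two (192) or
three (5) reagents, leaving 4668 analyzable proteins; 3 plates with 5
calibrator, 2 QC and 1 buffer samples each; 12 hybridization controls;
37% of patients in the latent high-risk group; 50 informative proteins
shifted by δ = 1.5 log2 units; true group log-SHR β₁ = ln 2; cause-1
asymptote p = 0.25 and rate λ₁ = 0.15/yr; competing-death rate
λ₂ = 0.04/yr; administrative censoring uniform on 6–13 years; clinical
missingness 53/6858. Under these defaults roughly 19% of patients reach
the HF endpoint and 25% die first, matching the event mix of the cohorts
the package emulates.

Event times follow the direct subdistribution parameterization
F₁(t|x) = 1 − [1 − p(1 − e^{−λ₁t})]^{exp(lp)} by inverse-CDF sampling,
with cause-2 times exponential conditional on not failing from cause 1.
The linear predictor is lp = β₁·1{group 2}: the latent group, not the
protein average, drives risk, so the true group SHR is exactly exp(β₁)
and recovery tests are sharp; the informative proteins are associated with
the outcome through the group. Measured RFU = 2^(true log2 level) ×
sample bias (uniform 0.7–1.4) × plate bias (uniform 0.9–1.1) × lognormal
noise (σ = 0.05); hybridization controls span 2⁵–2¹⁵ RFU and share the
sample and plate biases; pooled calibrator/QC samples carry the
population-average profile (including the group-mixture mean shift on
informative proteins); buffer samples are flat background. Clinical
tables contain 8 named variables (age, gender, ejection fraction,
diabetes, Killip ≥ 2, creatinine, BNP, NT-proBNP) correlated with the
latent group plus noise columns up to 27. One master seed drives
everything through per-component substreams, so paired
derivation/validation cohorts share the assay-level parameters while
patients, plates and follow-up differ.

What the generator does **not** emulate: per-protein marginal
distributions of any real assay, protein–protein correlation beyond the
group structure, echocardiographic remodeling, informative censoring,
plate-position or temporal drift effects, and per-protein effect-size
heterogeneity. Passing tests therefore demonstrate the correctness and
calibration of the algorithms under a faithful but idealized data
mechanism, not clinical performance on real cohorts.

## Problem sizes

The bundled benchmark experiments run at desk scale by design: the
familywise-error simulation uses 500 replicates of 150 patients × 200
proteins (the vectorized screen makes this a few seconds); the k-selection
benchmark 250 × 50; the normalization benchmark 3 plates × 500 SOMAmers;
recovery and coverage suites 50 seeds at n = 2000 and a 5-batch mean at
n = 3000. The full-scale assay shape (254 × 5284) is exercised where it is
cheap: bookkeeping, aggregation and threshold arithmetic.

## Known limitations

* Model-based (not sandwich) variance for Fine–Gray; no time-varying
  covariates, stratified baselines, or Gray's k-sample test.
* Single imputation only; multiple imputation is out of scope.
* The ADAT dialect is a deliberate simplification (three blocks, no vendor
  headers or checksums).
* Alternative cluster-count criteria (gap statistic, BIC, consensus
  clustering) are not implemented.
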