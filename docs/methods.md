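# Methods

This note documents the models, parameter choices and numerical decisions
behind `peaflow`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Generative model

### Protein abundances

True abundances live on the log2 scale.  For subject *i*, visit *v*,
protein *p*:

    x_ivp = mu_p + sex_p·1[male] + Σ_k beta_pk·g_ik + dis_p·1[T2D]
            + resp_p·1[responder] + b_ip + e_ivp,
    b_ip ~ N(0, σ²_between),  e_ivp ~ N(0, σ²_within).

Defaults: `mu_p ~ N(3, 1)` (log2 units above the extension-control level),
`σ_between = 0.4`, `σ_within = 0.1`.  The 4:1 ratio encodes the empirical
pattern that most plasma proteins vary far more between people than within
a person over a two-year window; it is also the regime in which the
inter- vs intra-CV decomposition should classify essentially all proteins
as inter-dominant, which the tests check.  Sex effects of ±0.5 log2 units
touch 20% of proteins, disease effects ±0.8 touch 10%, and a persistent
responder shift of ±1.0 touches 10% — large enough that the downstream
recovery checks measure pipeline behaviour rather than raw power, small
enough to stay in the range of reported plasma-proteome effect sizes.

### Cohorts and clinical values

Two cohorts are generated: a healthy longitudinal cohort ("wellness",
default 76 subjects, ages 50–65, ~40 males, 3 visits over ~2 years) and a
newly diagnosed T2D cohort (default 48 subjects, ~40 on metformin, visits
over ~3 months).  Fasting glucose, insulin and BMI are drawn with
cohort-dependent means (FPG 5.5 vs 9.0 mmol/L, insulin 8 vs 15 mU/L, BMI
26 vs 31 kg/m²) and small visit-to-visit noise.  Treated subjects carry a
planted response label; their total FPG decline is drawn inside the
corresponding classification band with a safety margin (responders
1.2–3.0, indeterminate 0.15–0.95, non-responders −0.3–0.05 mmol/L), so
label-recovery tests are meaningful without being tautological.

### Genotypes

Variants are biallelic, organised in LD blocks (default 4 variants,
200 kb spacing, 3 Mb between block starts, spread over 22 chromosomes).
Each haplotype copies a block founder allele drawn at the block MAF and is
independently redrawn with probability 0.1.  Marginally every variant is
Bernoulli(MAF) per haplotype — hence Hardy–Weinberg proportions at the
genotype level — while within-block r² is high (≈0.81 for adjacent
variants) and between-block r² is zero in expectation.  Causal variants
get a gene TSS planted within 1 Mb (cis) or on a different chromosome
(trans), so the cis/trans classifier can be scored against truth.

### Assay layer

Each well (study sample, negative, plate or sample control) draws, per
assay, `count ~ NegBin(mean = depth · 2^(plate + batch + abundance), φ)`
with variance `m + φ m²`.  Per-well depth is lognormal (mean 20,000,
CV 0.3); it cancels exactly in the extension normalization, which is the
point of the extension control.  Plate and batch offsets are *per assay*
(SD 0.5 and 0.4 log2 units) — a scalar per-plate factor would be
indistinguishable from depth and would make the plate-control adjustment
pointless.  The dispersion default `φ = 0.001` puts the counting-layer CV
at ~3–4% for well-detected assays (log2 SD ≈ 0.065 per measurement),
consistent with the precision of high-count sequencing read-outs; the
knob exists because overdispersion in real data varies by assay.
Negative-control wells use a constant background of −7 log2 units;
plate-control wells share one pool abundance vector (the protein means),
sample-control wells one reference vector.  Spiked extension / incubation /
amplification controls share the well depth and carry no plate or batch
offset; ~1% of wells receive a ±1.0 log2 incubation outlier so the QC
flag has something to find.  The amplification control is carried through
as a monitored value; no correction uses it.

The second-platform read-out is emitted directly on the NPX scale
(truth + per-protein offset SD 0.5 + noise SD 0.15): every cross-platform
comparison operates on NPX, so modelling qPCR cycle values would add
machinery without adding tested behaviour.

## Normalization and QC chain

Order of operations: extension ratio + log2 → incubation flagging → plate
adjustment → LOD.  Flagging precedes adjustment so a bad sample never
distorts another sample's values; the adjustment itself is driven purely
by plate-control wells.  Decisions:

* zero counts map to a pseudocount of 0.5 before the ratio (recorded in
  the NPX metadata);
* the per-assay anchor added back after the per-plate subtraction is the
  median over all plate-control wells across plates — it keeps a stable
  absolute level, makes the adjustment idempotent, and whether the
  vendor anchors to a global level or a reference plate is not public;
* the incubation QC value is the extension-normalized log2 ratio, so the
  ±0.3 threshold is in NPX-like units;
* LOD is `median + 3·SD` (sample SD) of negative-control NPX per assay
  per plate, with a +0.2 log2 fallback at zero SD; below-LOD values are
  annotated, never removed;
* bridging subtracts the per-assay median of paired differences over
  bridging samples (≥2 required); plate layouts spread bridge re-runs
  evenly over the target batch's plates, reserving capacity during
  packing if needed — concentrating bridges on one plate leaves that
  plate's adjustment noise uncancelled in the batch estimate;
* sample QC flags are total: flagged samples are excluded from analysis
  defaults but retained in every file.

## Variance decomposition

CV is computed on linearized values (2^NPX): CV is a ratio-scale
quantity, and NPX is a log unit.  An NPX-scale variant stays available
behind `linearize=False` for comparability with log-scale conventions.
Inter-CV is the mean over visits of the CV across individuals within a
visit; intra-CV the mean over individuals of the CV across visits.
Subjects with fewer than two visits (or visits with fewer than two
subjects) are skipped for the respective component.  The lognormal closed
form `CV = sqrt(exp(σ² ln²2) − 1)` is the test oracle; comparisons
account for the c4 small-sample bias of an SD estimated from 3 visits.

## pQTL mapping

The baseline phenotype is the per-subject median NPX across QC-pass
visits.  The scan is OLS on allele count + age + sex (sex 0/1, age in
years, no standardization: effects are NPX per allele), two-sided t-test
on the genotype term, computed via Frisch–Waugh–Lovell residualization
with a single shared QR when no genotypes are missing and per-variant
complete-case fits otherwise.  The significance threshold is
`5e-8 / n_proteins` by default with the divisor exposed.  Boundary and
tie policies: exactly 1 Mb from the TSS counts as cis; sentinel ties at
equal p break by chromosome then position; LD pruning applies only to
same-chromosome pairs within 1 Mb and tests candidate-vs-sentinel r²;
conditional refits add all sentinels selected so far as covariates and
keep candidates with conditional p < 0.01, iterating until exhausted.
Constant genotype columns are skipped with a recorded reason.

## Clinical associations and stratification

ANOVA differential expression fits the covariates first and tests the
factor last (nested-model F, the sequential ANOVA F for the final term).
When every protein shares one design matrix the F statistics are computed
with a single QR factorization; a test pins this path to per-protein
statsmodels fits.  Imbalance warns rather than fails.  A caution that the
test suite enforces on itself: for subject-level factors (sex, cohort),
repeated visits are pseudo-replicates and ANOVA across all visits is
anti-conservative — calibration holds at baseline-only, which is the
default for the cohort comparisons; repeated-measures questions belong to
the mixed model.  Fold change is the difference of factor-level NPX means
(NPX is already log2), second sorted level minus first.

Mixed-model associations use a random intercept per subject with fixed
effects for the clinical term + sex + age + visit.  P-values are Wald
tests from statsmodels' `MixedLM` rather than a Kenward–Roger correction:
the correction requires specialised machinery and the properties that are
actually asserted (type-I error calibration, slope recovery, the
inflation of OLS without the random intercept) are robust to the
approximation, as the simulations in the test suite show.  Significance
is BH-adjusted p < 0.01.

Stratification: baseline BMI > 30 is "obesity" (exactly 30 is not);
FPG decrease (first minus last visit) > 1 mmol/L is a responder, < 0.1 a
non-responder, the closed interval [0.1, 1] indeterminate; two
consecutive visit-to-visit changes of opposite sign, both above 1 mmol/L
in magnitude, override any net decrease to indeterminate.  Embeddings
(PCA, seeded UMAP) operate on per-protein standardized NPX; constant
proteins are dropped before scaling.

## Problem sizes

Defaults are desk-scale by design: 100 study proteins across 4 panels
(plus the three QC-assay proteins replicated per panel), 400 variants,
96-well plates.  The recovery analyses in the tests and the acceptance
script use the sizes at which their targets are statistically meaningful:
174–200 subjects for variance and offset recovery (6 plates × ~90
samples, 8 bridges), 10,000 tests for null calibration, 45,000 replicates
where a 95% coverage claim must be resolved against a 95.3% truth.

## What the synthetic data do not show

The generator reproduces the *structure* the analyses assume — additive
effects on log2 abundance, exchangeable Gaussian variance components,
negative-binomial counting noise, clean HWE, block LD with a hard
between-block cut.  Real plasma data add heavy-tailed and skewed protein
distributions, abundance-dependent technical variance (worse near LOD),
antibody cross-reactivity, population structure and relatedness,
medication and lifestyle confounding, and missingness that is not at
random.  Passing recovery tests therefore validates the computational
chain, not the biological robustness of any particular finding; analyses
of real cohorts should treat the pipeline's thresholds (all exposed in
`RunConfig`/provenance output) as starting points, not guarantees.
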