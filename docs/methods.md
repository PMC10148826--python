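# Methods

This note documents the models behind `ctcmet`, the parameters that
matter, what the synthetic-data generators do and do not emulate, and the
numerical and design choices made where the design was genuinely open.

## Differential screening (`ctcmet.screening`)

Bulk feature matrices (features × samples, intensities ≥ 0, NaN =
undetected) from two cell-line pairs are screened in a fixed order:
filter → impute → normalize → OPLS-DA / t-test → select → intersect.
Filtering and imputation are idempotent, so re-running a stage on its own
output changes nothing.

* **Detection filter.** A feature is removed only when its detection
  fraction is below 0.8 in *every* sample group; reaching 80% in any one
  group rescues it. This is the standard group-wise presence filter:
  a metabolite reliably seen in one biological condition is informative
  even if absent in the other. A second rule removes features whose
  maximum intensity is below 3× their blank noise level.
* **Imputation.** Missing entries become (feature's observed minimum)/10 —
  a left-censoring surrogate. Note its interaction with the t-test below:
  an imputed value is a large outlier on the log scale and inflates the
  within-group variance, which deliberately penalizes features whose
  evidence rests on sparsely detected values.
* **Normalization.** Per sample: divide by protein amount (µg) and by the
  spiked internal-standard intensity; per batch: divide each feature by
  its median across that batch's pooled-QC samples. Sample-level
  technical factors cancel exactly; QC division removes per-batch
  feature-level drift.
* **OPLS-DA.** NIPALS with a single predictive component for a two-group
  response; orthogonal components are added while 7-fold cross-validated
  Q² improves by more than 0.01, capped at 5 (the reference software's
  exact stopping heuristic is proprietary; a CV-improvement rule is the
  reproducible equivalent). Folds are deterministic venetian blinds
  stratified by class, so fits are seed-free. Features are autoscaled;
  constant features are dropped with a warning. VIP uses the predictive
  weight vector; with unit-norm weights VIPⱼ = √p·|wⱼ|, so ΣVIP² = p by
  construction.
* **Selection.** log₂FC is computed on linear-scale group means
  (metastatic over primary); p from a two-tailed equal-variance t-test on
  log₁₀ intensities (raw, no multiplicity correction); selected iff
  |log₂FC| > 1 ∧ p < 0.05 ∧ VIP > 1, all strict, so boundary values never
  pass. The candidate panel is the intersection of the selections from
  the two cell-line pairs, sorted.

## Single-cell quantification (`ctcmet.scquant`)

* **Extraction volume.** The filled nanocapillary tip is a cone frustum:
  radius a at the opening, half-angle α, meniscus height h along the
  axis. V = (πa³/(3 tan α))((1 + L tan α)³ − 1), L = h/a; µm inputs give
  fL directly. The cubic is expanded as x(3 + 3x + x²) to avoid
  cancellation, making the slender-cone limit V → πa²h exact to machine
  precision; the closed form agrees with numerical quadrature of
  ∫πr(x)²dx to <1e-8 relative over randomized geometries. A 100-nm tip
  (a = 0.05 µm, tan α = 0.1) filled to h = 22 µm holds ≈119 fL —
  the subpicoliter regime the platform extracts per cell.
* **Calibration.** OLS of the analyte/internal-standard response ratio on
  concentration. LOD = 3.3·σ_blank/slope and LLOQ = 10·σ_blank/slope
  (ICH blank-based convention; chosen because the assay's own definition
  is not stated); linear range runs from LLOQ to the highest standard.
  A non-positive slope is rejected as non-quantitative.
* **Back-calculation.** concentration = (ratio − intercept)/slope, with a
  below-LLOQ flag. Negative back-calculations clamp to 0 *with the flag
  set*: concentrations are physical and the downstream factorization
  requires non-negativity. A zero internal-standard signal refuses
  quantification instead of returning 0 — a missing spike means the
  extraction failed, not that the cell is empty.
* **Batch correction.** Parametric empirical-Bayes ComBat on log values:
  per-feature standardization by the size-weighted grand mean and pooled
  within-batch variance, per-batch location/scale estimates shrunk to
  their across-feature inverse-gamma/normal priors by the usual iterative
  posterior-mode solution, then back-transformation (output strictly
  positive). A single batch returns the input unchanged; a feature with
  zero variance inside a batch skips the scale step for that batch. The
  implementation matches Bioconductor `sva::ComBat` to ~1e-7 (log scale)
  on shared fixtures. Two caveats are inherent to ComBat, not defects:
  location removal is exact only when the standardized offsets are equal
  across features (the EB prior otherwise shrinks them), and the
  correction is only approximately idempotent because a second pass
  re-shrinks sampling noise (≲5% relative on realistic fixtures).
* **Precision.** RSD = 100·sd/mean (sample sd) per replicate group
  (intra-day) and on the pooled values (inter-day); the pass criterion is
  RSD ≤ 20%, the usual bioanalytical validation bound.

## Subtyping (`ctcmet.subtyping`)

* **NMF.** Lee–Seung multiplicative updates for squared Frobenius error,
  random uniform initialization, ε = 1e-12 denominators; the objective is
  recorded per iteration and is non-increasing; stops at 1e-5 relative
  improvement or 2000 iterations. Hard labels are the argmax of each
  cell's basis coefficients.
* **Consensus clustering.** Per candidate rank k ∈ 2..6: 30 NMF restarts
  from seeds spawned off the root seed; consensus matrix = mean
  connectivity of the per-run partitions. The cophenetic correlation of
  the (1 − consensus) distances against their average-linkage dendrogram
  picks the rank (ties → smaller k); consensus labels come from cutting
  that dendrogram, not from any single run. If the consensus distances
  are constant (perfectly stable clustering) the cophenetic coefficient
  is defined as 1.
* **Column scaling.** Before factorization each metabolite is divided by
  its cohort mean (`column_scale=True`). Raw mM concentrations span an
  order of magnitude across the panel, and the Frobenius objective would
  otherwise be dominated by the highest-abundance metabolite (on
  synthetic cohorts, per-run label agreement with planted truth falls
  from ~0.95 to ~0.66 without scaling). Scaling by a positive constant
  per column preserves non-negativity and cluster geometry. `nmf()`
  itself never rescales its input.
* **Fingerprint selection.** Backward elimination on a logistic
  regression of the binary cluster label against standardized panel
  metabolites: drop the largest-Wald-p metabolite while any p ≥ α
  (default 0.05); survivors ordered by |standardized coefficient|. At the
  default α each uninformative metabolite survives with probability ≈ α,
  so *exact* recovery of a planted fingerprint requires multiplicity
  control (e.g. α/p, Bonferroni) — the tests exercise both regimes.
* **Risk model.** Maximum-likelihood logistic regression of C2 membership
  on raw mM fingerprint abundances; natural-log coefficients and
  intercept are divided by ln 10 so the stored model is on the base-10
  logit scale of the published formula (scores are identical under this
  reparametrization). The score threshold is the Youden cutoff of the
  training scores. Orientation of "C2": an explicit `high_risk_label`
  argument wins; otherwise, with patient outcomes available, the cluster
  whose per-patient count correlates positively with metastasis;
  otherwise the larger cluster label, deterministically. (A "provisional
  fit" cannot anchor the orientation: whichever cluster is coded 1 ends
  up with the higher mean fitted risk.) Whether the original model was
  fit against cluster labels or patient outcomes is ambiguous in the
  source; this package fits against cluster labels.
* **Published model.** `published_risk_model()` returns the printed
  constants verbatim: coefficients (−0.932, 3.967, −0.166, −1.822) for
  (glutamic, malic, aspartic, lactic) acid per mM, intercept −3.694,
  threshold 0.420. `risk_score` matches inputs by metabolite *name*,
  refuses missing metabolites, and returns scores clamped to the open
  unit interval at the nearest representable doubles (the sigmoid
  saturates in floating point for |logit| ≳ 16).
* **Separation handling.** All logistic fits fall back to a ridge
  (λ = 1) Newton fit with Wald statistics from the penalized Hessian when
  statsmodels hits complete separation or fails to converge; such fits
  are flagged with a warning. λ ≪ 1 would defeat the purpose: under
  separation the penalized SE is ≈ 1/√λ and every Wald test goes null.
* **Youden cutoff.** Candidates are the unique observed scores; positive
  iff score ≥ cutoff; ties in J = sensitivity + specificity − 1 resolve
  to the smallest cutoff. Candidate midpoints are deliberately not used —
  observed values keep the cutoff data-driven and deterministic, and the
  maximizer is invariant under strictly increasing transforms.

## Patient-level classification (`ctcmet.patient_risk`)

Cell calls aggregate to per-patient (total, C1, C2) counts; roster
patients without cells get zero counts and a `ctc_negative` flag and are
excluded from classifier evaluation (the typing system only applies to
CTC-positive patients). AUC is the tie-aware Mann–Whitney probability
(midranks), identical to trapezoidal ROC integration when there are no
ties. Count classifiers are strict: positive iff count > cutoff for total
and C2 counts, count < cutoff for C1 (low C1 is unfavorable). The strict
boundary is anchored in the prospective-cohort behavior, where a C2 count
exactly at the cutoff (1) was favorable. Count cutoffs are chosen by
maximizing Youden's J over observed counts. Logistic association reports
per-predictor odds ratios with Wald 95% CIs, univariately and jointly
(all predictors entered, no selection).

`implied_confusion` reconstructs the integer confusion matrix behind a
reported (sensitivity, specificity) pair on a cohort of known group
sizes, trying both assignments of the groups to positive/negative and
keeping the one that reproduces both printed rates at 1-decimal rounding.
For the 60-patient training split (33/27) this resolves a legend
ambiguity in the source: only 33 positives / 27 negatives is
integer-consistent with the printed rates.

## Synthetic data (`ctcmet.synthetic`)

The generators define the study conditions under which the pipeline is
tested.

* **Noise model.** Biological noise is multiplicative log-normal with σ
  chosen so the CV equals the requested RSD (concentrations are positive
  and variation is reported CV-style). Batch effects are additive in log
  space per batch and feature — exactly the location/scale family ComBat
  assumes. Bulk missingness is MCAR (the source does not characterize its
  missingness mechanism).
* **Bulk screens.** Two feature matrices (one per cell-line pair) share
  their planted differential set; planted features carry an exact
  2^(log2fc_effect) mean ratio (default 4×), 9 replicates per line,
  feature-wise log-uniform baselines (10⁴–10⁶), technical
  protein/internal-standard factors that the normalization cancels, and a
  per-batch QC sample equal to that batch's feature-wise mean profile.
  Replicate i of both lines lands in batch i mod n_batches, so batch
  composition is balanced across groups and expected fold changes are
  preserved.
* **CTC cohorts.** Each patient draws a CTC count from the clinical
  distribution (1: 3.3%, 2: 6.7%, 3: 30%, ≥4: 60%; the ≥4 mass split
  30/20/10 over 4/5/6, a choice the source leaves open) and a C2
  propensity from Beta(2, 2), so subgroup mixing varies between patients
  and intra-patient heterogeneity exceeds the within-subgroup RSD. Cells
  draw their subgroup, then concentrations = baseline centroid ×
  log-normal noise (default RSD 0.60) × mild batch factor (RSD 0.05).
  C2 centroids are 4× the C1 baseline on the four fingerprint metabolites
  and identical elsewhere; the all-up direction follows the screening
  observation that the candidate metabolites are elevated with metastatic
  potential (the source reports no per-metabolite C1-vs-C2 effect sizes,
  so the shift magnitude is a free parameter). Metastasis is Bernoulli
  with natural logit −2.2 + 1.1·(true C2 count), i.e. risk rises from 10%
  with no C2 cells to ~87% with four — outcomes depend on the C2 count
  only, so the C2-count classifier should dominate the total count, and
  it does.
* **What the generators do not emulate.** Real chromatograms, spectra and
  retention behavior; intensity-dependent (left-censored) missingness;
  correlated metabolite panels; CTC-negative patients' outcomes;
  patient-level covariate structure (age, sex, stage, CEA, CA 19-9 are
  not simulated). Passing tests therefore demonstrate the correctness and
  internal consistency of the algorithms under the stated statistical
  structure, not clinical performance on real cohorts — in particular,
  the published cohort AUCs (0.927 / 0.681) are not reproducible from
  synthetic data and are not targets.
* **Recovery experiment.** `simulate_from_risk_model` draws independent
  log-normal fingerprint concentrations and Bernoulli labels from the
  published score. Its design — glutamic (1.2 mM, RSD 0.6), malic
  (1.85, 0.25), aspartic (3.0, 1.2), lactic (1.2, 0.5) — is an
  identifiability design, not a cohort emulation: the means center the
  logit near its decision region, the malate spread is moderated because
  its 3.967/mM coefficient otherwise saturates the logit (cells far from
  the boundary carry no Fisher information), and the wide aspartate
  spread makes its small coefficient (0.166/mM) estimable at n = 5000
  (Wald SE ≈ 0.010 on the base-10 scale under this design).

## Problem sizes

The test suite and acceptance script use 20-seed batteries with 60-patient
cohorts (≈230 cells) for classifier properties, ~300-cell cohorts at 30%
RSD for rank selection, n = 5000 cells for coefficient recovery, and 1000
random geometries for the volume check; the end-to-end discovery chain
runs on 6 seeds. These sizes give stable pass/fail behavior for the
properties asserted while keeping a full run on one CPU in the
single-digit minutes.

## Known limitations

* The published risk model applied to *synthetic* cohorts is
  intentionally not a good classifier: the generator plants all-up
  shifts, while the published coefficients (fit to real CTC data) have
  mixed signs. Synthetic end-to-end checks therefore always refit the
  risk model; the published constants are exercised for exactness, not
  synthetic performance.
* ComBat's EB shrinkage makes batch-mean removal exact only in the
  equal-offset case and idempotence approximate (see above).
* OPLS-DA component selection reproduces the spirit, not the letter, of
  the proprietary reference implementation; Q²/R² values are comparable
  but not bit-identical to it.
* The backward-elimination fingerprint at α = 0.05 retains extra panel
  metabolites at the type-I rate; exact-set recovery needs a corrected α.
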