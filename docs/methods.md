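# Methods

`uromet` implements an end-to-end analysis of untargeted urine LC–MS
metabolomics for gestational-age (GA) estimation in pregnancy: curation and
normalization of a feature-abundance table, random-forest regression of GA at
sample collection with external leave-one-out cross-validation (LOOCV),
parsimonious panel selection, term/preterm stratified comparison, univariate
association and correlation-network analyses, and MS/MS library annotation.
Because the package is developed and tested without access to patient data,
it ships a synthetic-cohort generator whose structure mirrors a multi-site
pregnancy study; all recovery tests run against that generator's known ground
truth.

## Synthetic cohorts (`uromet.simulate`)

The generator emulates a discovery cohort of 99 subjects sampled once between
8 and 19 weeks' gestation (GA uniform over that window), roughly half of whom
go on to deliver preterm (< 37 weeks), plus an independent 20-subject
term-only validation cohort. For feature *f* and subject *s*:

    log A_fs = baseline_f + slope_f · GA_s + bio_fs

* `baseline_f ~ N(6, 1.5²)` in natural log of spectral counts;
* `slope_f` is non-zero for `n_informative` features (default 30 of 2000);
  55% of slopes are positive, magnitudes uniform on 0.08–0.18 log-units per
  week (2.4–9-fold change over the sampled GA window, the scale on which
  steroid conjugates rise in pregnancy urine);
* `bio_fs ~ N(0, biological_log_sd²)` is per-subject biological variation
  (default SD 0.30).

Each injection then multiplies the subject's abundance vector by
(i) log-normal technical noise (SD 0.10), (ii) the sample's urine dilution
factor (log-normal, SD 0.50 — urine concentration varies several-fold with
hydration), (iii) a smooth per-batch injection-order drift curve, and (iv) a
small per-site offset (log-SD 0.05: with harmonized collection protocols,
site effects are minor and sites largely overlap in ordination).

Design features reproduced:

* **Acquisition layout** — four batches; a QC pool (equimolar mixture of all
  study samples) injected every 10 positions and at each batch end; two
  blanks per batch; a 5-level QC dilution series (0.125–1×, an 8× range);
  1–4 technical replicates per sample with mean ≈ 1.75 (≈172 injections from
  99 samples).
* **Drift** — each batch has a shared smooth sensitivity trend (linear +
  sinusoidal in normalized injection order, relative amplitude
  `drift_amplitude`, default 0.15) plus a smaller per-feature deviation;
  multiplicative, as MS sensitivity drift is.
* **Missingness** — left-censoring: values below the `missing_quantile`
  (default 5%) of the pre-censoring study-injection distribution become
  missing. This is what low-value imputation assumes; missingness is *not*
  random.
* **Blank signal** — features appear in blanks at 1% of baseline except a
  planted contaminant subset (default 10) present at study-like levels, so
  the blank filter has a defined target. A further subset (default 8) has a
  saturating (flat) dilution-series response to exercise the linearity
  filter.
* **Preterm variability** — for subjects destined to deliver preterm and
  sampled between weeks 14 and 17, the biological SD of informative features
  is inflated by `preterm_var_multiplier` (default 2×): higher
  inter-individual variability of predictive metabolites in that window,
  rather than a shift in their mean trajectories, is the mechanism by which
  preterm pregnancies resist accurate GA prediction.

What the generator does **not** emulate: raw spectra or chromatographic peak
shapes, correlated metabolite families arising from shared pathways (except
via the explicit `generate_correlated_blocks` helper used in network tests),
adducts/isotopes mapping one metabolite to several features, non-monotone GA
trajectories, and retention-time drift. Passing recovery tests therefore
demonstrates that the pipeline's estimators are consistent under the stated
noise model, not that the biological findings generalize.

Determinism contract: identical `SimConfig` (including `seed`) gives
bit-identical outputs; the validation cohort draws from an independent
stream derived from the same seed, reusing the discovery ground truth
(baselines, informative features, slopes) so trained models transfer.

## Preprocessing (`uromet.preprocess`)

Stages in order, each behind a scikit-learn-style transformer:

1. **Blank filter** — remove features with mean(blank) ≥ 0.5 · mean(QC pool)
   (missing counted as zero signal). No threshold is standard in the
   literature; 0.5 is conventional and configurable. Blanks are audit-only
   and are dropped from the table afterwards.
2. **Dilution-linearity filter** — Pearson r of abundance vs dilution level
   across the QC dilution series; r < 0.6 discards the feature. Missing
   series values count as zero abundance; an undefined r (zero variance) is
   treated as failing. Pearson (not Spearman) is used for the lowercase-r
   convention of calibration linearity.
3. **Presence filter** — keep features non-missing in strictly more than 2/3
   of study injections ("present" = non-missing): 67/99 passes, 66/99 does
   not.
4. **LOESS drift correction** — per feature and batch, degree-1 LOESS
   (span 0.75, no robustness iterations) of QC-pool abundance vs injection
   order; the correction factor at any order is the fitted value
   (interpolated between QC orders, held flat beyond the terminal QCs)
   divided by the median fitted value; every injection in the batch is
   divided by its factor. Division rather than subtraction, consistent with
   multiplicative MS error. Non-positive fitted values are clamped to the
   smallest positive fitted value; batches with fewer than 5 QC pools are
   left uncorrected with a logged warning.
5. **PQN** — reference spectrum = per-feature median over QC pools (scope
   configurable to all study injections); per injection the factor is the
   median quotient against the reference over features observed in both;
   an injection sharing fewer than 10 features with the reference is an
   error. After normalization every injection's median quotient is exactly 1.
6. **Low-value imputation** — missing entries of an injection are drawn
   uniformly from (0.5·m, m) where m is that injection's minimum observed
   value; seeded. This matches left-censored missingness.
7. **Replicate aggregation** — identity (1 replicate), mean (2), median
   (3–4; also >4 with a warning).
8. **Mode merge** — independently preprocessed HILIC and RPLC tables are
   concatenated by feature id; metabolites detected in both modes remain
   distinct features.

Filters are idempotent; the pipeline records per-stage feature/injection
counts in a JSON-lines provenance log.

## GA prediction (`uromet.predict`)

`TunedForestRegressor` wraps a random-forest regressor (default 500 trees)
whose feature fraction per split {0.1, 0.33, 0.5} and minimum leaf size
{1, 3, 5} are tuned by internal 5-fold CV minimizing RMSE; a single-cell
grid skips the search. The external loop is leave-one-out: for each sample,
tuning and training happen on the remaining n−1 samples only (the held-out
sample never influences model selection), and the aggregated out-of-fold
predictions give Spearman ρ, its two-sided P, and RMSE in weeks. A constant
prediction vector makes ρ undefined; it is reported as 0 with P = 1.

Feature importance is impurity-based, averaged over the LOOCV fold models,
with ties broken by feature id. The **restricted (parsimonious) panel** is
chosen by forward inclusion in importance order: for k = 1..max_k the LOOCV
RMSE is computed with the top-k features, and the selected k is the smallest
whose RMSE lies within one standard error of the minimum (1-SE rule; the SE
of the minimizing panel's RMSE comes from its per-sample squared errors via
the delta method, sd(e²)/(2·RMSE·√n)). Stratified models repeat LOOCV and
selection independently within the term and preterm groups. A validation
cohort is always preprocessed with its own LOESS/PQN statistics before the
discovery-trained panel model predicts it — no cross-cohort leakage.

GA at delivery can be substituted as the target, but single-timepoint urine
profiles are not expected to predict it; the package makes no term/preterm
outcome classifier.

## Association, networks, annotation

* **Screen** — per-feature Spearman ρ and two-sided P against GA, significant
  at raw P < 0.05 (deliberately uncorrected, as a descriptive screen;
  Benjamini–Hochberg available via `correct="bh"`). The volcano effect size
  is the OLS slope of log2 abundance on GA (log2-fold change per week),
  computed on unscaled log2 abundances.
* **PCA axes** — features are standardized; the two principal components
  whose scores correlate most strongly with GA (|Spearman ρ|) are reported,
  since the GA direction need not dominate total variance.
* **Bin CV** — coefficient of variation (SD/mean) of *raw* normalized
  abundances per GA bin (default edges 8, 11, 14, 17, 19 weeks), separately
  for term and preterm groups; CV of log-transformed data is not meaningful,
  so this is the one analysis done on the raw scale. Empty or zero-mean bins
  yield NaN.
* **Pathway ORA** — one-sided Fisher exact (enrichment) test per
  user-supplied pathway set over an explicit background; no m/z-based
  putative pathway mapping is attempted.
* **Network** — all pairwise Spearman correlations among model-selected
  metabolites; edges kept when the Bonferroni-adjusted P (denominator =
  number of pairs tested, m(m−1)/2) is ≤ 0.01; weight |ρ| with the sign as
  an attribute (both signs qualify). Betweenness centrality is unnormalized
  and computed on the unweighted graph for determinism (a 1/|ρ|-distance
  weighted variant is available); layout is seeded Fruchterman–Reingold.
* **Annotation** — candidates gated by ±15 ppm precursor m/z and, for
  library entries with retention times, ±30 s (HILIC) / ±20 s (RPLC).
  Similarity is the forward dot-product with square-root intensity weighting
  and greedy one-to-one fragment pairing within ±15 ppm (closest m/z first;
  a max-weight assignment variant is available via `pairing="optimal"`):
  score = (Σ paired w_q·w_r)² / (Σ w_q² · Σ w_r²) ∈ [0, 1]. Annotations
  scoring ≥ 0.4 report MSI level 1 (in-house entry: m/z + RT + fragments) or
  level 2 (public spectral match); below-threshold or unmatched features are
  level 4, and level 3 marks caller-supplied putative identities. Fragment
  tolerance and intensity weighting are package conventions (the common
  spectral-search defaults) and are configurable.

## Problem sizes in tests and the acceptance script

The default modeling configuration (500 trees, 3×3 tuning grid) is intended
for real analyses. The test suite and `scripts/acceptance.py` run the same
code paths at reduced sizes chosen to finish quickly on a single CPU: 100
trees with a fixed hyperparameter combination (feature fraction 0.1, minimum
leaf 3), the default 2000-feature cohort for preprocessing-recovery and
headline LOOCV checks, and smaller cohorts (150–400 features, 60–99
subjects) for the repeated-seed experiments (permutation null, restricted-
panel recovery, stratified mechanism). These sizes are package choices
documented here; the assertions they feed are fixed.

## Known limitations

* LOESS fitting loops over features; very large tables (≫10⁴ features) would
  benefit from vectorization.
* The 1-SE rule's SE estimate ignores the correlation between LOOCV folds,
  as is conventional; panel sizes should be read as approximate.
* Impurity-based importances are biased toward high-cardinality features;
  permutation importance is available but slower.
* The network stage tests m(m−1)/2 pairwise hypotheses with Bonferroni,
  which is conservative for correlated features.
* The simulator's missingness is purely abundance-censoring; real tables mix
  censoring with sporadic technical dropouts.
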