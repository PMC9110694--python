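# uromet

Urine-metabolomics analysis of gestational age (GA): a tested, reusable
pipeline for estimating GA at the time of sample collection from an
untargeted LC–MS feature table.

Accurate pregnancy dating drives clinical decisions, yet early obstetric
ultrasound is often unavailable in low-resource settings. Urine is an
attractive alternative sample — non-invasive, sterile, protein-poor — and
pregnancy progression leaves a strong metabolic signature in it (steroid
hormone conjugates in particular). `uromet` implements the full analysis
such a study needs, from raw feature table to a parsimonious metabolite
panel:

* **QC-driven preprocessing** — blank filtering, dilution-linearity
  filtering (Pearson r < 0.6 discards), a strict "> 2/3 of samples"
  presence filter, per-batch LOESS (span 0.75) drift correction on pooled-QC
  injections, probabilistic quotient normalization (PQN) against a median
  reference to remove urine-dilution effects, low-value imputation of
  left-censored missingness, and technical-replicate aggregation
  (mean of 2, median of 3–4), with HILIC/RPLC mode merging.
* **Prediction** — random-forest regression of GA (weeks) with internal-CV
  hyperparameter tuning inside an external leave-one-out loop, reported as
  Spearman ρ, P, and RMSE over the aggregated blinded predictions; forward
  selection in importance order with a 1-SE rule yields the smallest
  metabolite panel that retains predictive ability; independent validation
  cohorts are preprocessed with their own statistics before the panel model
  is applied. Term and preterm strata are modeled separately.
* **Interpretation** — per-feature Spearman screening with log2 volcano
  betas, GA-correlated PCA axes, coefficient-of-variation analysis across
  GA bins, one-sided Fisher-exact pathway over-representation,
  Bonferroni-thresholded Spearman correlation networks with betweenness
  centrality and Fruchterman–Reingold layout, and MS/MS library annotation
  by forward dot-product similarity with MSI confidence levels.
* **Synthetic cohorts** — a seeded generator (`uromet.simulate`) reproducing
  the structure of a multi-site study (99 discovery + 20 validation
  subjects, GA uniform on 8–19 weeks, batches with QC pools every 10
  injections, dilution series, blanks, replicates, left-censored
  missingness, a GA-informative feature minority with 55%/45% mixed slope
  signs) so the whole pipeline is testable end-to-end with known ground
  truth.

The modeling components are scikit-learn estimators
(`uromet.predict.TunedForestRegressor`, the transformer classes in
`uromet.preprocess`) and compose with sklearn tooling; the module-level
functions are thin wrappers over them.

## Worked example

Simulate a small cohort, preprocess it, and fit the LOOCV models from the
command line:

```bash
cat > cfg.yaml <<EOF
simulate:
  n_subjects: 24
  n_validation: 10
  n_features: 150
  n_informative: 8
  n_batches: 2
  qc_every: 5
model:
  n_trees: 100
  feature_fractions: [0.33]
  min_leaf_sizes: [3]
restricted_max_k: 5
EOF
uromet run-all --config cfg.yaml --seed 3 --out-dir run1
```

This writes the cohort tables, the preprocessed matrix, prediction CSVs,
`metrics.json`, the association table, the correlation network
(GraphML + edge/node tables) and a `manifest.json`; rerunning with the same
config and seed reproduces every file byte-for-byte. The same pipeline from
Python:

```python
from uromet.simulate import SimConfig, generate_cohort
from uromet import preprocess, predict

table, meta, truth = generate_cohort(SimConfig(seed=1))
matrix, log = preprocess.run_preprocessing(table, meta, seed=1)

X = matrix.T  # samples x features
study = meta[meta.type == "study"].drop_duplicates("sample_id").set_index("sample_id")
y = study.loc[X.index, "ga_weeks"]

cfg = predict.ModelConfig(n_trees=100, feature_fractions=(0.1,), min_leaf_sizes=(3,), seed=1)
result = predict.loocv_predict(X, y, cfg)
panel = predict.select_restricted_model(X, y, cfg, result=result)
print(f"rho={result.rho:.2f}  RMSE={result.rmse:.2f} weeks  panel k={panel.k}")
```

On this simulated cohort the full model reaches a cross-validated Spearman
ρ ≈ 0.95 with RMSE ≈ 1.2 weeks, and the restricted panel (here 8–9
metabolites, all of them truly GA-informative in the generator's ground
truth) retains that accuracy — GA predicted to about a week from a handful
of urine metabolites, which is the pipeline's point.

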