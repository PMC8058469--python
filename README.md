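# metaboscan

A tested, reusable pipeline for case/control analysis of GC-MS untargeted
plasma metabolomics data:

- **QC-pool drift normalization** — each study-run intensity is divided by
  the median of the three chronologically nearest pool injections, per
  channel.
- **RSD filtering** — channels with relative standard deviation ≥ 20% are
  excluded (four selectable RSD populations: raw pools, leave-one-out
  normalized pools, normalized study runs, replicate CV).
- **Statistical scans** — two-tailed Welch's t-tests with Benjamini–Hochberg
  adjustment over replicate-averaged metabolite values and over all pairwise
  metabolite-ratio features (ratios computed within each replicate run, then
  averaged per subject).
- **Classifier** — a from-scratch two-class simple-logistic model fitted by
  LogitBoost with single-attribute weighted-least-squares base learners; the
  iteration count is chosen by stratified 10-fold cross-validation; five
  training-data variants (raw / averaged / averaged+RSD / ratios /
  ratios+metabolites); evaluation with confusion metrics, ROC and
  rank-based AUC, overall and per age stratum (G1 19–34, G2 35–50,
  G3 51–67 years).
- **Synthetic data generator** — emulates the assumed acquisition design
  (72+72 subjects, technical duplicates, pool injections after every 8 study
  runs, 262 channels, multiplicative run-order drift, planted log-fold-change
  effects) so every stage is testable without external data.

## CLI

All functionality is exposed through the `metaboscan` command:

```sh
# generate a synthetic dataset (intensity.tsv, metadata_runs.tsv,
# metadata_subjects.tsv, truth.tsv)
metaboscan simulate --seed 1 --out data/

# pool-based drift normalization
metaboscan normalize --intensity data/intensity.tsv \
    --runs data/metadata_runs.tsv --out norm.tsv --report normreport.tsv

# RSD QC (writes the per-channel table; optionally the filtered matrix)
metaboscan qc --intensity-raw data/intensity.tsv --intensity-norm norm.tsv \
    --runs data/metadata_runs.tsv --mode pools_raw --threshold 0.20 \
    --out rsd.tsv --filtered-out filtered.tsv

# Welch + BH scans
metaboscan scan --features metabolites --intensity filtered.tsv \
    --runs data/metadata_runs.tsv --subjects data/metadata_subjects.tsv \
    --out results_metabolites.tsv
metaboscan scan --features ratios --intensity filtered.tsv \
    --runs data/metadata_runs.tsv --subjects data/metadata_subjects.tsv \
    --out results_ratios.tsv

# train + evaluate the ratio-feature classifier
metaboscan train --variant ratios --intensity-norm norm.tsv \
    --intensity-filtered filtered.tsv --runs data/metadata_runs.tsv \
    --subjects data/metadata_subjects.tsv --k 10 --max-iterations 60 \
    --seed 1 --model-out model.tsv --cv-out cv.json
metaboscan evaluate --model model.tsv --intensity-norm norm.tsv \
    --intensity-filtered filtered.tsv --runs data/metadata_runs.tsv \
    --subjects data/metadata_subjects.tsv --subgroups age_group \
    --report evaluation.json --roc roc.tsv

# or everything at once from a YAML config (see metaboscan/pipeline.py
# DEFAULT_CONFIG for the schema; omitting input paths simulates)
metaboscan run-all --config config.yaml --out outdir/
metaboscan report --out outdir/
```

File formats are plain TSV: a wide intensity matrix
(`run_id<TAB>channel...`), a run table
(`run_id, run_index, sample_type, subject_id, replicate_id`), a subject
table (`subject_id, group, age, age_group`), and results tables
(`feature_id, kind, mean_case, mean_control, t, df, p, p_adj`). Models are
serialized as a plain-text table of base learners plus standardization
constants.

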