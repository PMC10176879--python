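# nps-ehr

Classify 13 neuropsychiatric-symptom (NPS) categories in free-text clinical
notes, estimate misclassification-corrected prevalence, and quantify
agreement between note-derived symptoms and NPI proxy-questionnaire
assessments. Because real memory-clinic EHR corpora are private, the package
ships a fully parameterized synthetic corpus generator so every stage runs
and is tested against known ground truth.

## What it does

- **`nps_ehr.synthetic_corpus`** — generates patient-level note clusters with
  lexical cue phrases per category (optionally inside negations such as
  "no depressive symptoms"), gold labels, paired imperfect annotator views,
  and NPI-style domain-score tables, all deterministic under a seed.
- **`nps_ehr.annotation_io`** — reads/writes brat standoff `.ann`/`.txt`
  pairs (text-bound annotations, 0-based end-exclusive offsets verified
  against the document) and reduces spans to document × category label
  matrices.
- **`nps_ehr.preprocessing`** — tokenization, negation-phrase removal
  (cue + window, truncated at sentence boundaries), stop-word removal,
  pluggable stemming (identity or built-in Porter), and unigram/bigram
  counting into a sparse document-term matrix with document-frequency
  pruning. External corpora are featurized against the frozen training
  vocabulary only.
- **`nps_ehr.classification`** — one elastic-net-penalized logistic
  classifier per category (unpenalized intercept, internal unit-variance
  standardization), stratified tenfold cross-validation with out-of-fold AUC
  hyperparameter selection, Youden-index cutoff selection on out-of-fold
  scores, and frozen-model external validation guarded by a vocabulary
  hash. Categories with fewer than 10 positives are refused as untrainable.
- **`nps_ehr.prevalence`** — Rogan–Gladen corrected prevalence with
  adjusted-Wald confidence intervals that propagate validation-set
  sensitivity/specificity uncertainty (unclamped by default), an AUC ≥ 0.80
  reporting gate, and two-group prevalence comparisons with
  Benjamini–Hochberg FDR control.
- **`nps_ehr.agreement`** — Cohen's kappa and accuracy for annotator pairs
  (document level), NPI presence at thresholds 1 and 4, and EHR-vs-NPI
  discordance proportions (EHR+NPI−, EHR−NPI+).
- **`nps_ehr.pipeline_cli`** — orchestrates the whole experiment from one
  YAML config and writes CSV/JSON tables plus a manifest (config hash +
  seed); reruns with the same config and seed are byte-identical.

## Command line

```sh
# full experiment (synthetic or from_files mode) from one config
nps-ehr run --config run.yaml

# generate a synthetic corpus: .txt docs, gold labels CSV, per-rater brat
# .ann views, NPI table
nps-ehr simulate --config synth.yaml --out simdir/

# document-level agreement between two brat annotation directories
nps-ehr agree --ann-a simdir/rater_a --ann-b simdir/rater_b
```

A minimal `run.yaml`:

```yaml
mode: synthetic
seed: 13
out_dir: runs/demo
gate: 0.8
train_synthetic:
  n_patients: 500
  seed: 13
external_synthetic:
  n_patients: 250
  center: B
  seed: 14
preprocess:
  min_document_frequency: 5
classifier:
  alpha_grid: [0.1, 0.55, 1.0]
  n_lambda: 10
  cv_folds: 10
```

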