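# offtarget-bias

Tools for studying how the **provenance of activity data biases off-target
QSAR classifiers** — and what to do about it.

Public bioactivity databases (ChEMBL-style extracts) are dominated by
*active* compounds: positive results are published preferentially, and most
entries come from on-target optimization campaigns. Pharmaceutical
safety-screening collections are the mirror image, dominated by
*inactives*. Binary classifiers inherit the skew of their training domain:
a model trained on active-rich public data over-predicts activity (high
false-positive rate), while a model trained on inactive-rich proprietary
data over-predicts inactivity (high false-negative rate). This package
implements the full analysis pipeline that exposes, quantifies, and
exploits that opposing bias — runnable entirely on synthetic two-domain
data, so no database access is required.

## What it does

- **`synthetic_data`** — generates valid drug-like SMILES from a fragment
  grammar with a shared latent structure–activity rule (substructure
  anchors → pChEMBL-scale potency), sampled into an active-majority
  "public" domain and an inactive-majority "proprietary" domain, with
  optional curation hazards (salts, duplicates, stereoisomer pairs with
  agreeing/conflicting labels, inorganics, molecular-weight outliers) and
  a machine-readable truth sidecar.
- **`curation`** — structure standardization to the neutral organic parent,
  median merging of assay potencies, pChEMBL-threshold labeling (≥ 5
  active; threshold 6 supported), stereo-stripped-InChI deduplication
  (conflicting stereoisomer labels drop the whole group), the
  \>1000-compound / ≥15%-inactive target-selection filter, release-tag
  time-series splits, molecular-weight windowing (61–2323 Da) and
  seen-compound exclusion.
- **`featurize`** — ECFP4/1024 fingerprints for modeling, ECFP6/4096 for
  similarity analysis; exact Tanimoto similarity (scalar and matrix).
- **`model`** — a single-hidden-layer feed-forward classifier with
  **class-weighted binary cross-entropy**
  `L = −mean(w₁·y·log p + w₀·(1−y)·log(1−p))`, `w_c = N/(2·N_c)`,
  trained with Adam (lr 0.01, ×0.1 on 10-epoch training-loss plateau,
  early stopping after 20), a 288-point hyperparameter grid search
  selected by validation MCC, stratified 5-fold cross-validation, and a
  fixed 0.5 classification threshold.
- **`metrics`** — the nine confusion-matrix statistics (sensitivity,
  specificity, BA, ACC, PPV, NPV, recall, F, MCC) with explicit
  `UNDEFINED` markers for zero-denominator cells instead of silent NaNs.
- **`consensus`** — both-models-agree risk flagging of screening sets,
  with explicit active/inactive/discordant accounting.
- **`prediction_space`** — UMAP embedding of a screening set under the
  hybrid distance `D_tot = (1−w)·D_struct + w·D_pred` (`D_struct` =
  Tanimoto distance, `D_pred` = mean absolute difference of the two
  models' probabilities, default `w = 0.05`), graded by an
  XGBoost-on-coordinates ROC AUC against a shuffled-coordinate null.
- **`applicability`** — exact nearest-training-neighbor Tanimoto profiling,
  leakage checks (similarity ≥ 0.99), and correctness-split histograms.
- **`pipeline` / `cli`** — the full study as one call (`run_study`) or as
  shell subcommands (`offtarget-bias synth|curate|train|predict|eval|consensus|embed|ad|all`).

## Worked example

```python
from offtarget_bias.pipeline import run_bias_experiment, run_prediction_space_experiment
from offtarget_bias.model import TrainConfig

bias = run_bias_experiment(seed=7, n_per_domain=600, n_test=300,
                           train_config=TrainConfig(hidden_units=64, batch_size=64, max_epochs=60))
print(f"public-domain model : FPR={bias.public_fpr:.3f}  FNR={bias.public_fnr:.3f}")
print(f"private-domain model: FPR={bias.private_fpr:.3f}  FNR={bias.private_fnr:.3f}")

cons, emb, qual = run_prediction_space_experiment(bias, seed=7, n_screening=300)
s = cons.summary()
print(f"screening actives   : public={s['public']['actives']}  private={s['private']['actives']}  consensus={s['consensus']['actives']}")
print(f"embedding AUC       : real={qual.auc_real:.3f}  null={qual.auc_null:.3f}")
```

prints

```
public-domain model : FPR=0.514  FNR=0.088
private-domain model: FPR=0.087  FNR=0.456
screening actives   : public=200  private=91  consensus=84
embedding AUC       : real=0.690  null=0.472
```

Read it as: on one balanced, train-disjoint test set, the model trained on
the 80%-active domain errs almost exclusively by calling inactives active
(FPR 0.51 vs FNR 0.09), while the model trained on the 20%-active domain
shows the mirror-image error profile. On an unlabeled screening set the
public model flags 200/300 compounds, the private model 91/300, and only
84 survive the consensus — the flags on which two oppositely biased models
agree. The prediction-space embedding is informative: a classifier given
only the 2D coordinates recovers the (median-binarized) model output with
AUC 0.69, while shuffled coordinates sit at chance.

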