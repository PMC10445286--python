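# Methods

## The problem

Off-target activity models for safety pharmacology are trained on whatever
labeled chemistry is available. Publicly curated potency data are heavily
enriched in actives — publication bias plus on-target optimization — while
industrial safety-screening collections are enriched in inactives. The
package's core question is how that *domain composition*, rather than the
chemistry itself, shapes a classifier's error profile, and how two
oppositely biased models can be combined (consensus flags, joint
prediction-space maps) into something more reliable than either alone.

## Data model and curation

A compound record is a raw structure (SMILES), a list of pChEMBL-scale
potency observations (pChEMBL = −log10 molar potency; 5 ≈ 10 μM, 6 ≈ 1 μM),
a release tag, and a target id. Curation proceeds:

1. **Standardization** — RDKit `rdMolStandardize`: cleanup, largest organic
   fragment (drops salts/solvents/counterions), charge neutralization.
   Records that fail to parse or have no carbon / non-organic elements are
   removed with a reason; a batch is never aborted by one bad row.
2. **Assay merging** — multiple potencies for one compound–target pair are
   merged by the **median**, robust to one outlying assay and equal to the
   mean of the middle pair at even counts.
3. **Labeling** — active iff potency ≥ threshold (default 5). The boundary
   is deliberately *active*: only strictly sub-threshold compounds are
   inactive.
4. **Deduplication** — on stereo-stripped InChI, because ECFP fingerprints
   carry no stereochemistry. A duplicate group with one consistent label
   keeps a single representative (lexicographically smallest full InChI —
   deterministic and seed-free); conflicting labels drop the whole group,
   since no fingerprint model could resolve the contradiction.
5. **Target selection** — model a target only if it has > 1000 compounds
   and ≥ 15% inactives. The ≥15% test uses the unrounded percentage;
   reports round to 2 decimals, so a target at exactly the boundary is
   not decided by rounding.
6. **Time-series split** — train on records with release tag ≤ cut, test
   on later tags, with test duplicates of training compounds dropped
   (stereo-agnostic). This emulates prospective validation.
7. **Auxiliary filters** — molecular-weight window 61–2323 Da (inclusive
   bounds; the range of the training corpora), exclusion of compounds seen
   in any reference set, and metadata predicates (human, single protein,
   IC50/Ki) for raw activity exports.

## The synthetic two-domain generator

Real extracts are replaced by a generator whose point is *statistical*
fidelity, not chemical realism (no synthesizability, no matching of real
property distributions):

- **Structures** come from a fragment grammar — 12 scaffold templates ×
  40 × 40 substituents (19,200 molecules), all valid SMILES by
  construction. A grammar (rather than random graphs) is used so the
  activity signal lives in recurring substructures that ECFP models can
  learn; without learnable signal, a bias study would only measure noise.
- **Potency** = 4.7 + Σ (anchor matches × signed contribution) + N(0, 0.4)
  on the pChEMBL scale. Anchors are SMARTS patterns (basic amines,
  pyridines, sulfonamides push potency up; acids, nitro groups, nitriles,
  esters push it down), giving a latent pool ~56% active at threshold 5.
  The Gaussian term is seeded by a stable hash of the canonical SMILES, so
  potency is a deterministic function of (rule, structure): a compound
  sampled into both domains carries identical potency, which is what makes
  "same chemistry, different sampling" a meaningful experimental contrast.
- **Domains** are quota samples from a seed-shuffled enumeration: the
  public spec draws 80% actives, the proprietary spec 20%, the evaluation
  spec 50%. If the rule cannot fill the quotas within 10× oversampling the
  generator fails loudly, naming the gap. Label noise (default 0.02 in the
  canonical specs — a small assay-error surrogate chosen once) reflects
  that fraction of potencies across the threshold.
- **Hazards** are injected as *extra* records at `round(rate·n)` each:
  salt adducts and duplicates of clean parents, stereoisomer pairs built
  on a chiral template (agreeing or threshold-straddling potencies),
  carbon-free inorganics, and MW outliers. A JSON truth sidecar records
  exactly what was injected, so curation tests assert exact set algebra
  rather than summary statistics.

What passing tests on this generator do **not** show: robustness to real
assay heterogeneity (mixed readouts, inter-lab variation), realistic
chemical-series correlation structure, or covariate shift between real
public and industrial chemistry. They show that the pipeline's logic —
curation, weighting, selection, consensus, embedding — behaves as designed
when the ground truth is known.

## Classifier

A single hidden layer (ReLU) with sigmoid output on ECFP4/1024 inputs,
trained by minimizing class-weighted binary cross-entropy

    L = −mean( w_pos · y · log p + w_neg · (1−y) · log(1−p) ),
    w_c = N / (2 · N_c),

so a minority-class error costs more and the loss reduces exactly to
unweighted BCE at class balance. One hidden layer is the minimal
architecture consistent with a single hidden-units hyperparameter; the
trainer is a compact NumPy implementation (He/Xavier init, inverted
dropout, Adam), which keeps every training run bit-deterministic for a
fixed seed on any platform.

Optimization: Adam at lr 0.01; after each epoch the full-training-set loss
(dropout-free) is recorded; lr ×0.1 on a 10-epoch plateau of that loss
(floor 1e−5); early stopping after 20 epochs without improvement; hard cap
`max_epochs` (500 default — a termination guarantee, usually unreached
because early stopping fires first). Inference applies no dropout; binary
calls use a fixed 0.5 threshold with p = 0.5 classified active (the same
≥ convention as potency labeling).

Hyperparameters: hidden units 256–2048 (step 256) × input dropout 0–0.2 ×
hidden dropout 0.2–0.4 (steps 0.1) × batch size 64–256 (step 64) = 288
configurations, each trained on a stratified 80% split and scored on the
20% validation split; the best validation **MCC** wins (MCC is the most
informative single number under class imbalance), ties broken by higher
balanced accuracy, then fewer hidden units, then smaller batch.
Cross-validation is stratified 5-fold at one fixed configuration.

## Metrics

The nine statistics are computed literally from the confusion matrix, with
a zero denominator producing an explicit `UNDEFINED` marker that
propagates (undefined precision makes F undefined; any empty margin makes
MCC undefined). This matters precisely for the models this package
studies: a model that never predicts the positive class has TP = FP = 0
and an *undefined*, not zero, precision. Report views round half-even at
2 decimals; reference comparisons allow ±0.005, with one documented
exception — published balanced-accuracy cells that equal the mean of
already-rounded sensitivity/specificity are accepted under that same
chain-rounding convention.

## Consensus

A screening compound is flagged **active** only when both domain models
call it active, **inactive** when both call it inactive, and **discordant**
otherwise — three explicit cells that partition the set, never folding
disagreement into "inactive". Because the two models err in opposite
directions, the intersection trims each model's characteristic false
calls; on synthetic screens the consensus actives' mean latent potency
exceeds either single model's.

## Prediction-space embedding

Pairwise distance for UMAP:

    D_tot = (1 − w) · D_struct + w · D_pred
    D_struct = 1 − Tanimoto(fp_i, fp_j)
    D_pred   = ( |Δp_public| + |Δp_private| ) / 2

A convex combination was chosen because it matches both limits (purely
structural at w = 0 — exact equality, not approximate — and purely
prediction-coherent at w = 1) and keeps D_tot in [0, 1]; using the mean
over both models' probabilities makes the coherence term symmetric in the
two domains. Default w = 0.05: small enough to preserve structural
clusters, large enough to pull prediction-coherent compounds together
(pure structural distance over-weights moieties that explode into many
fingerprint bits, e.g. bulky aliphatic cages). UMAP runs on the
precomputed matrix with n_neighbors = 15, min_dist = 0.1 and a fixed
random state; labels never enter except through the w-weighted term.

Embedding quality: binarize one model's probabilities at their **median**
(ties to the positive class — a near-balanced target by construction),
train XGBoost on the 2D coordinates, report stratified 5-fold CV ROC AUC,
and compare against the same procedure on row-shuffled coordinates,
averaged over 5 independent shuffles to tame the Monte-Carlo error of a
single permutation. Degenerate (all-identical) probability vectors are
rejected rather than silently producing a one-class target.

## Applicability domain

For each test/screening compound, the maximum Tanimoto similarity to any
training compound on ECFP radius-3/4096-bit fingerprints (longer vectors,
fewer collisions, a sharper similarity scale), computed exactly by matrix
algebra — datasets here are desk-scale, so no approximate nearest-neighbor
search is warranted. Similarity ≥ 0.99 flags leakage; stereoisomers of
training compounds score exactly 1.0 because the fingerprints are
stereo-blind. The relation between correctness and nearest-train
similarity is *reported* (0.05-wide histogram bins, split by correctness)
but not asserted — it is empirically only a weak tendency.

## Tanimoto conventions and numerics

- All-zero vs all-zero fingerprints: similarity 1.0 (identical objects);
  all-zero vs non-zero: 0.0. Totality matters for degenerate inputs.
- The matrix path multiplies in float32 (exact for integer bit counts
  far below 2²⁴) and divides in float64, so matrix and scalar results are
  bitwise identical.
- Folded-fingerprint bit collisions are accepted as-is; no count vectors.

## Study-scale choices

The canonical study conditions are 2000 compounds per domain, a 600-
compound balanced evaluation pool (train-disjoint, typically ~380 after
exclusion), 400–600-compound screening sets, and training capped at 150
epochs (early stopping usually fires well before). These sizes give stable
estimates of the bias pattern (FPR/FNR gaps of ~0.3 against Monte-Carlo
noise of a few points) and desk-scale runtimes. The unit-test suite uses
smaller instances of the same constructions.

## Known limitations

- The generator's chemistry is combinatorial, not realistic; absolute
  performance numbers do not transfer to real corpora, only the
  qualitative contrasts.
- The trainer is CPU-only and single-threaded by design; the 288-point
  grid at full data scale is compute-heavy and meant for batch use.
- Probability calibration, applicability-weighted prediction, and
  alternative learners are out of scope.
- With only two models, consensus cannot distinguish "both right" from
  "both wrong in the same direction"; it cancels *opposing* biases only.
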