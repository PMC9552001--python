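# reprotox

A consensus machine-learning pipeline for predicting **rat multigeneration
reproductive toxicity** of chemicals from molecular-descriptor tables.

Guideline multigeneration reproductive toxicity studies dose two or more
generations of rats and score reproductive endpoints; they are slow,
expensive and animal-intensive, so in-silico screening from 2D chemical
structure is an attractive triage step. This package implements, as a
tested and reusable library + CLI, the full modeling workflow for that
problem: a chemical is represented by a row of numeric molecular
descriptors (Mold2-style, 777 columns nominally), labeled *positive* when
a reproductive LOAEL (lowest-observed-adverse-effect level, mg/kg/day) was
recorded for it, and classified by an ensemble of seven models combined by
majority vote.

## What the pipeline does

1. **Descriptor selection** (three stages, the first two label-blind):
   - drop descriptors that are zero in **> 90%** of training chemicals;
   - drop descriptors with Shannon entropy **< 2.5 bits** over 20
     equal-width bins spanning the training min–max,
     `H = −Σ pᵢ log₂ pᵢ`;
   - repeated 5-fold CV fitting decision-tree, decision-forest and
     random-forest models; a descriptor's importance per algorithm is its
     usage frequency normalized by the maximum frequency, averaged over
     the three algorithms; keep descriptors with overall importance
     **> 0.2**.
2. **Seven base classifiers** behind one fit/predict-probability contract:
   decision tree (DT), decision forest (DF), random forest (RF),
   k-nearest neighbors (kNN), support vector machine (SVM), linear
   discriminant analysis (LDA) and logistic regression (LR). Each has an
   explicit positive-class probability: leaf fraction (DT), mean of tree
   leaf fractions (DF/RF), neighbor fraction (kNN), Platt sigmoid of the
   margin fitted by internal 5-fold CV (SVM), two-class posterior (LDA),
   logistic sigmoid (LR). The DF is an ensemble of trees constrained to
   **pairwise-disjoint descriptor sets**, grown sequentially.
3. **Hyperparameter tuning** by inner cross-validation: on a stratified
   80% subset, five repeats of 5-fold CV per candidate setting, choosing
   the setting with the highest mean Matthews correlation coefficient
   (MCC).
4. **Consensus model**: a chemical is positive iff more than 3 of the 7
   base models vote positive, with probability

       N⁺ > 3 :  p = 1 − (7 − N⁺)/8
       N⁺ ≤ 3 :  p = N⁺/6

5. **Evaluation**: repeated 5-fold cross-validation (500 iterations at
   paper scale; the quick profile uses 20) and external validation,
   scored by seven metrics — accuracy, sensitivity, specificity, balanced
   accuracy, positive/negative predictive rate and MCC.
6. **Prediction confidence**: `confidence = |p − 0.5| / 0.5`, binned into
   ten equal ranges with per-bin accuracy and a count-weighted rank
   correlation between confidence and accuracy.
7. **LOAEL-stratified sensitivity**: sensitivity computed separately for
   strong positives (LOAEL ≤ 100 mg/kg/day) and weak ones (> 100).
8. **Applicability domain**: PCA of the standardized training
   descriptors, components retained to 95% cumulative variance, Euclidean
   distance of every chemical to the training-score centroid, and a
   Mann–Whitney comparison of training vs external distance
   distributions.

Because curated descriptor tables for the original study are not
deposited in machine-readable form, the package ships a first-class
**synthetic study generator** (`reprotox.synthetic_data`) that emulates
the data structure — 275 training chemicals (94 positive / 181 negative),
777 descriptors with heterogeneous scales, sparse and near-constant
columns, LOAELs spanning four orders of magnitude anti-correlated with a
latent severity score, and a 29-chemical external set (18 positive)
shifted away from the training centroid — so every stage is testable
end-to-end with no downloads.

## Worked example

```bash
reprotox generate --out study --seed 21 --n-train 60 --n-external 20 \
    --n-descriptors 30 --effect-size 3.0
reprotox filter --descriptors study/train_descriptors.csv \
    --labels study/train_labels.csv --out filt --iterations 2 --seed 1
# -> kept 15 of 30 descriptors
reprotox crossval --descriptors filt/filtered_descriptors.csv \
    --labels study/train_labels.csv --specs specs.json --out cv \
    --iterations 2 --seed 4
```

prints the per-model means over the CV iterations (untuned default
specs in `specs.json`):

```
           accuracy  sensitivity  specificity  balanced_accuracy  positive_predictive_rate  negative_predictive_rate    mcc
model
DT            0.750        0.690        0.782              0.736                     0.633                     0.826  0.466
DF            0.608        0.452        0.692              0.572                     0.445                     0.701  0.145
RF            0.800        0.571        0.923              0.747                     0.805                     0.801  0.547
kNN           0.667        0.286        0.872              0.579                     0.542                     0.694  0.193
SVM           0.725        0.405        0.897              0.651                     0.675                     0.738  0.353
LDA           0.800        0.690        0.859              0.775                     0.725                     0.837  0.556
LR            0.817        0.690        0.885              0.788                     0.761                     0.842  0.589
consensus     0.792        0.548        0.923              0.735                     0.798                     0.791  0.526
```

Read: on this small synthetic study every model clears chance
(balanced accuracy > 0.5, MCC > 0), all models are more specific than
sensitive — the characteristic pattern with 94:181-style class
imbalance — and the consensus sits among the stronger individual
models. `reprotox run
--config config.yaml --out rundir` executes the entire pipeline
(generate/ingest → filter → tune → CV → confidence → LOAEL strata →
external validation → applicability domain) and writes every report plus
a manifest with the seed and configuration hash; `reprotox report
--run-dir rundir` summarizes a finished run.

## Layout

| module | role |
| --- | --- |
| `reprotox.dataio` | descriptor/label table I/O, validated joins, reports |
| `reprotox.synthetic_data` | study generator with ground truth |
| `reprotox.feature_filter` | sparse / entropy / tree-importance selection |
| `reprotox.learners` | the seven classifiers incl. the decision forest |
| `reprotox.tuning` | inner-CV grid search maximizing MCC |
| `reprotox.consensus` | 7-vote majority rule and its probability model |
| `reprotox.evaluation` | repeated CV, metrics, LOAEL strata, external validation |
| `reprotox.confidence` | confidence binning and trend analysis |
| `reprotox.chemspace` | PCA-centroid applicability domain |
| `reprotox.pipeline`, `reprotox.cli` | orchestration and the `reprotox` command |

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
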