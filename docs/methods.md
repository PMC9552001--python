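# Methods

This note documents the models and procedures implemented in `reprotox`,
the defaults and the reasoning behind them, what the synthetic study
generator does and does not emulate, and the numerical conventions used
where the underlying formulas are ambiguous or degenerate.

## Problem setting

A chemical is a row of numeric molecular descriptors (Mold2-style; the
descriptor software itself is an upstream black box — tables are
consumed, never computed here). The label is binary: *positive* when a
reproductive LOAEL (lowest-observed-adverse-effect level, mg/kg/day) was
recorded in a rat multigeneration study, *negative* otherwise. The task
is binary classification with a roughly 1:2 positive:negative imbalance,
which is why MCC — not accuracy or balanced accuracy — drives
hyperparameter selection.

## Descriptor selection

Three stages, applied to the training table only:

1. **Sparse filter** — remove descriptors zero in strictly more than 90%
   of training chemicals.
2. **Entropy filter** — for each descriptor, bin the training values into
   20 equal-width bins spanning [min, max] (top bin right-closed so the
   maximum lands in bin 20, avoiding a phantom empty bin) and compute
   `H = −Σ pᵢ log₂ pᵢ` with `0·log₂0 = 0`. Remove descriptors with
   H strictly below 2.5 bits; a descriptor at exactly 2.5 is kept. The
   boundary convention is a package decision — the two stated
   inequalities ("greater than 2.5 kept", "less than 2.5 removed") leave
   equality undefined — and is recorded in every `FilterReport`.
3. **Tree-frequency importance** — repeated 5-fold CV; on each 4-fold
   training part fit a decision tree, a decision forest and a random
   forest, and record the set of descriptors each fitted model actually
   splits on (counted once per model instance). Importance per algorithm
   is frequency divided by the maximum frequency over descriptors;
   overall importance is the mean over the three algorithms. Keep
   descriptors with overall importance strictly above 0.2.

Stages 1–2 never see the labels and are asserted label-permutation
invariant in the tests; stage 3 legitimately uses labels but only inside
its own cross-validation.

**Stage-3 model capacities.** The usage-frequency statistic only
discriminates when a model cannot afford to split on everything: an
unconstrained 100-tree random forest touches essentially every
descriptor in every fit, driving all normalized importances to 1 and
making the filter a no-op. The stage-3 models are therefore compact —
DT with `max_depth=10`, DF with 5 trees of depth ≤ 10, RF with 10 trees
of depth ≤ 5 — so that descriptor choice is a scarce resource and
frequency reflects genuine preference. On the default synthetic study
this stage behaves like the intended funnel (777 → 505 → ~400 → tens of
descriptors, with all truly informative descriptors retained).

Stage-3 CV folds are unstratified uniform random (a `stratified` flag is
available), and 500 iterations is the paper-scale default; tests and the
acceptance script use 20, which is ample for a stable frequency ranking
at these problem sizes.

## Base classifiers and probability contracts

| model | implementation | positive-class probability |
| --- | --- | --- |
| DT  | sklearn decision tree | fraction of positive training chemicals in the leaf |
| DF  | this package | mean of member-tree leaf fractions |
| RF  | sklearn random forest | mean of member-tree leaf fractions |
| kNN | sklearn k-neighbors | fraction of positives among the k neighbors |
| SVM | sklearn SVC + sigmoid calibration | `1/(1+exp(A·f+B))`, A,B fitted by internal 5-fold CV |
| LDA | sklearn LDA | two-class posterior (sigmoid of the discriminant) |
| LR  | sklearn logistic regression | logistic sigmoid of the linear score |

Conventions and deviations, all recorded in run manifests:

- An exponential-only form of the LDA "probability" is unbounded and
  cannot be a probability; the standard normalized two-class posterior is
  the only probability-valued reading and is what is implemented.
- The SVM kernel is unspecified in the source description; the default
  here is RBF. Calibration uses `CalibratedClassifierCV(..., cv=5,
  ensemble=False)`, which is exactly Platt scaling with maximum-likelihood
  A, B estimated on internal 5-fold cross-validated margins.
- Distance/margin methods (kNN, SVM, LDA, LR) standardize descriptors by
  training mean/sd inside the fitted pipeline; tree-based models consume
  raw values. Descriptor scales vary over orders of magnitude, so
  unstandardized distances would be dominated by a few columns.
- The class rule everywhere is **positive iff probability ≥ 0.5** (0.5 is
  the minimum probability at which a chemical is called positive).

**Decision forest.** Trees are grown sequentially; after each tree, the
descriptors it split on are withheld from all later trees, so descriptor
sets are pairwise disjoint and each descriptor informs at most one tree.
If descriptors run out before the requested tree count the forest stops
early with a warning (at least two trees are required; otherwise fitting
fails). The ensemble probability is the unweighted mean of the member
trees' leaf fractions. Member trees are sklearn decision trees; the
disjoint-feature construction and the ensemble are this package's.

## Hyperparameter tuning

Tuning runs on a stratified 80% subset drawn once per run from the
master seed; the remaining 20% never influences the choice (ID-level
disjointness is asserted). For each candidate setting: five repeats of a
5-fold CV; each repeat's MCC is computed on the repeat's pooled held-out
predictions; the setting with the highest mean MCC wins, ties breaking
to the first-listed setting (recorded). The grids are conventional
ranges (DT depth/leaf, RF size/features, DF tree count, kNN k, SVM C/γ,
LR C) — the source names none — and are written verbatim into the
tuning report. A pruned `QUICK_GRIDS` variant exists for smoke runs and
the acceptance script.

## Consensus model

Exactly seven votes (base-model labels, never averaged probabilities);
subsets are refused since the probability formulas hard-code seven.
Positive iff N⁺ > 3, with probability `1 − (7 − N⁺)/8` when N⁺ > 3 and
`N⁺/6` otherwise. At N⁺ = 3 the rule as printed yields label *negative*
with probability exactly 0.5 — in tension with the "probability ≥ 0.5 ⇒
positive" convention used for base models. It is implemented exactly as
stated (label negative, probability 0.5, confidence 0) and flagged in
reports rather than silently repaired.

## Evaluation

Repeated k-fold CV: each iteration draws a fresh unstratified fold plan
(fold sizes differ by at most one; every chemical held out exactly once,
asserted on every run) from an iteration-indexed seed derived from the
master seed. All seven models are fitted per fold; consensus votes are
combined per chemical within the iteration; the seven metrics are
computed on the iteration's pooled predictions, then aggregated as mean
and standard deviation over iterations.

MCC uses the Matthews denominator
`sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))`; a widely-circulated variant that
repeats two factors is not the Matthews coefficient (it can exceed 1)
and is not used. Degenerate denominators: MCC → 0; sensitivity,
specificity, PPR, NPR → undefined (NaN, excluded from aggregation and
never coerced to 0).

External validation refits the seven models on the full training set and
scores the external chemicals; training/external ID overlap is refused
by name. LOAEL stratification splits positives at 100 mg/kg/day
(strong ≤ 100 < weak) and computes per-model sensitivity from the pooled
prediction log; an empty stratum is reported as undefined, not 0.

## Prediction confidence

`confidence = |p − 0.5| / 0.5`, symmetric in the classes; the
absolute value is required for the stated [0, 1] range to hold on both
sides of the boundary. Predictions are pooled across iterations into ten
equal bins `[0,0.1), …, [0.9,1.0]` (top bin closed). The trend summary is
a count-weighted rank correlation between bin index and bin accuracy;
constant accuracy maps to 0, and occupied bins holding under 1% of
predictions are flagged as statistically fragile.

## Applicability domain

Training descriptors are standardized (training mean/sd; zero-variance
descriptors dropped with a warning) and decomposed by PCA; the smallest
number of leading components reaching 95% cumulative variance is
retained (a fixed component count can be requested instead). Every
chemical is projected and its Euclidean distance to the training-score
centroid computed, along with the training-distance quantile ("farther
than 95% of training chemicals"). Distances of the two groups are
compared with a two-sided Mann–Whitney test — rank-based because the
distance distributions are right-skewed and no named test is prescribed.
By default the PCA consumes the post-selection descriptors; a flag
allows the entropy-filtered superset.

## Synthetic study generator

The generator emulates the *statistical shape* of the study data, not
chemistry:

- **Composition**: 275 training chemicals, 94 positive / 181 negative
  (exact assignment by default; Bernoulli optional); external set of 29
  with 18 positives.
- **Descriptors** (777): a block of informative columns (34 by default,
  matching the selected-descriptor count of the motivating study) whose
  standardized means shift by `effect_size` in positives; a sparse block
  (272 — the count the motivating study's zero-filter removed) zero in
  95% of chemicals; the remainder split between continuous noise with
  log-normal scale heterogeneity and non-negative count-like columns
  with log-uniform Poisson rates, a share of which is near-constant so
  the entropy filter has realistic work to do.
- **Labels** ride on a latent Gaussian severity score (positives
  ~N(1, 0.35), clipped positive; negatives 0) that also scales each
  positive's descriptor shift, so stronger positives are more separable.
- **LOAEL**: log10 doses evenly spaced over four orders of magnitude
  (0–4, i.e. 1–10,000 mg/kg/day), assigned to positives by the rank of a
  Gaussian copula mixing −severity with noise. The default mixing gives
  a Spearman correlation of about −0.8 between LOAEL and severity
  (anything ≤ −0.5 satisfies the design intent); −1 reverses ranks
  exactly.
- **External shift**: informative-descriptor means of every external
  chemical displaced by `shift_magnitude` standard deviations
  (default 0.5 in the study-shaped configuration) — a covariate shift
  that reproduces the qualitative applicability-domain picture: external
  chemicals sit farther from the training centroid and external
  performance trails cross-validation.
- **Determinism**: one master seed; every sub-stream (roles, column
  parameters, labels, latent scores, values, LOAEL copula) derives a
  fixed-key child seed, so identical configurations are byte-identical.

What it does **not** emulate: real descriptor covariance or
block-correlation structure, discreteness patterns of actual Mold2
output, or any chemistry. Passing tests therefore demonstrate that the
pipeline's machinery is correct and that its qualitative behaviors
(consensus gain, confidence–accuracy trend, LOAEL effect, domain-shift
degradation) emerge under controlled conditions — not that any
particular real-data accuracy would be achieved.

## Problem sizes and profiles

Paper-scale defaults (500 CV iterations, 500 importance iterations, full
grids) are available throughout; the package's quick profile — 20 CV
iterations, 20 importance iterations, pruned grids — is used by the test
suite and `scripts/acceptance.py`, chosen because aggregate metric means
stabilize well before 20 iterations at n ≈ 275 while keeping a full run
under a minute. The acceptance script derives all randomness from its
`--seed` and is fully deterministic.

## Known limitations

- The consensus probability takes only nine values; its confidence bins
  are coarse by construction.
- kNN and DT probabilities are rationals with small denominators, so DT
  predictions cluster at extreme confidence — per-bin DT metrics outside
  the top bin rest on few predictions and are flagged as sparse.
- Subset consensus (fewer than seven models) is deliberately
  unsupported.
- Missing descriptor values are rejected rather than imputed; imputation
  is out of scope.
- The generator's dials (effect size, shift, anti-correlation) are study
  conditions, not fitted quantities; they were chosen once for realism
  and are not tuned to test outcomes.
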