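"""Repeated 5-fold cross-validation, the seven performance metrics,
LOAEL-stratified sensitivity, and external validation.

Per iteration the dataset is randomly split into folds of near-equal size
(sizes differ by at most one), all seven base models are fitted on the
complement of each held-out fold, the consensus vote is taken per chemical
from the seven held-out predictions, and the seven metrics are computed on
the iteration's pooled predictions.  Fold randomization uses
iteration-indexed seeds derived from the master seed.

Metric conventions for degenerate confusion matrices: MCC with a zero
denominator is 0; sensitivity, specificity, PPR and NPR with a zero
denominator are undefined (NaN, excluded from aggregation).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from reprotox._rng import derive_seed
from reprotox.consensus import N_MODELS, consensus_predict
from reprotox.dataio import LabeledDataset
from reprotox.learners import ALGORITHMS, LearnerSpec, classify, fit

__all__ = [
    "MODEL_ORDER",
    "CONSENSUS",
    "FoldPlan",
    "ConfusionCounts",
    "MetricSet",
    "CVResult",
    "ExternalResult",
    "make_folds",
    "confusion_from_predictions",
    "compute_metrics",
    "run_repeated_cv",
    "loael_stratified_sensitivity",
    "external_validate",
]

CONSENSUS = "consensus"
MODEL_ORDER = ALGORITHMS + (CONSENSUS,)
METRIC_NAMES = (
    "accuracy",
    "sensitivity",
    "specificity",
    "balanced_accuracy",
    "positive_predictive_rate",
    "negative_predictive_rate",
    "mcc",
)


@dataclass(frozen=True)
class FoldPlan:
    """Per-chemical fold assignment for one CV iteration."""

    assignment: np.ndarray  # int in {0..folds-1}
    folds: int
    seed: int

    def __post_init__(self) -> None:
        a = np.asarray(self.assignment, dtype=int)
        object.__setattr__(self, "assignment", a)
        sizes = np.bincount(a, minlength=self.folds)
        if sizes.max() - sizes.min() > 1:
            raise ValueError(f"fold sizes must differ by at most 1, got {sizes.tolist()}")
        if (a < 0).any() or (a >= self.folds).any():
            raise ValueError("fold assignment out of range")

    def sizes(self) -> list[int]:
        return np.bincount(self.assignment, minlength=self.folds).tolist()


def make_folds(
    n: int, folds: int = 5, seed: int = 0, stratified: bool = False, y: np.ndarray | None = None
) -> FoldPlan:
    """Random fold assignment of n chemicals into near-equal folds.

    Unstratified by default; with ``stratified=True`` each class is dealt
    round-robin so class proportions are preserved per fold.
    """
    if folds < 2:
        raise ValueError("folds must be at least 2")
    if n < folds:
        raise ValueError(f"cannot split {n} chemicals into {folds} folds")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    if stratified:
        if y is None:
            raise ValueError("stratified folds require labels")
        y = np.asarray(y)
        offset = 0
        for cls in np.unique(y):
            rows = np.flatnonzero(y == cls)
            rows = rows[rng.permutation(len(rows))]
            assignment[rows] = (np.arange(len(rows)) + offset) % folds
            offset += len(rows)
    else:
        order = rng.permutation(n)
        base, extra = divmod(n, folds)
        start = 0
        for f in range(folds):
            size = base + (1 if f < extra else 0)
            assignment[order[start : start + size]] = f
            start += size
    return FoldPlan(assignment, folds, seed)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    positive_predictive_rate: float
    negative_predictive_rate: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    t = np.asarray(y_true, dtype=int)
    p = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        tp=int(((t == 1) & (p == 1)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def compute_metrics(counts: ConfusionCounts) -> MetricSet:
    """The seven metrics from a confusion matrix.

    MCC uses the Matthews denominator
    sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); a zero denominator yields MCC 0.
    """
    if counts.total < 1:
        raise ValueError("at least one prediction required")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    denom = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom > 0 else 0.0
    return MetricSet(
        accuracy=(tp + tn) / counts.total,
        sensitivity=sens,
        specificity=spec,
        balanced_accuracy=(sens + spec) / 2.0,
        positive_predictive_rate=_ratio(tp, tp + fp),
        negative_predictive_rate=_ratio(tn, tn + fn),
        mcc=mcc,
    )


@dataclass(frozen=True)
class CVResult:
    """Per-iteration metrics for the 8 models plus the full prediction log.

    ``per_iteration`` columns: iteration, model, the seven metrics.
    ``predictions`` columns: iteration, model, id, true, probability, predicted.
    """

    per_iteration: pd.DataFrame
    predictions: pd.DataFrame
    iterations: int
    folds: int
    seed: int

    def aggregate(self) -> pd.DataFrame:
        """Mean and standard deviation of each metric per model (NaN-excluded)."""
        g = self.per_iteration.groupby("model", sort=False)[list(METRIC_NAMES)]
        agg = pd.concat({"mean": g.mean(), "sd": g.std(ddof=1)}, axis=1)
        return agg.reindex([m for m in MODEL_ORDER if m in agg.index])


def _check_specs(specs: Mapping[str, LearnerSpec]) -> None:
    missing = [a for a in ALGORITHMS if a not in specs]
    if missing:
        raise ValueError(f"specs for all {N_MODELS} base algorithms required; missing {missing}")


def run_repeated_cv(
    dataset: LabeledDataset,
    specs: Mapping[str, LearnerSpec],
    iterations: int = 500,
    folds: int = 5,
    seed: int = 0,
    stratified: bool = False,
) -> CVResult:
    """Repeated k-fold cross-validation of the 7 base models + consensus.

    Every chemical is held out exactly once per iteration; the consensus
    vote for a chemical combines the seven base labels from the same
    iteration; per-iteration metrics are computed on the iteration's
    pooled predictions.
    """
    if iterations < 1:
        raise ValueError("iterations must be at least 1")
    _check_specs(specs)
    n = dataset.n_chemicals
    rows_metrics: list[dict] = []
    rows_pred: list[pd.DataFrame] = []
    ids = np.array(dataset.ids)

    for it in range(iterations):
        plan = make_folds(
            n, folds=folds, seed=derive_seed(seed, 11, it), stratified=stratified, y=dataset.y
        )
        probs = {alg: np.full(n, np.nan) for alg in ALGORITHMS}
        for fold in range(folds):
            test_rows = np.flatnonzero(plan.assignment == fold)
            train_rows = np.flatnonzero(plan.assignment != fold)
            train_ds = dataset.take(train_rows)
            if len(np.unique(train_ds.y)) < 2:
                warnings.warn(f"single-class training part at iteration {it}, fold {fold}")
                continue
            test_table = dataset.table.take(test_rows)
            for alg in ALGORITHMS:
                learner = fit(specs[alg], train_ds)
                probs[alg][test_rows] = learner.predict_proba(test_table)

        covered = ~np.isnan(probs[ALGORITHMS[0]])
        base_labels = {alg: classify(np.nan_to_num(probs[alg], nan=0.0)) for alg in ALGORITHMS}
        vote_matrix = np.column_stack([base_labels[alg] for alg in ALGORITHMS])
        n_pos, cons_label, cons_prob = consensus_predict(vote_matrix)

        frames = []
        for alg in ALGORITHMS:
            frames.append(pd.DataFrame({
                "iteration": it, "model": alg, "id": ids[covered],
                "true": dataset.y[covered], "probability": probs[alg][covered],
                "predicted": base_labels[alg][covered],
            }))
        frames.append(pd.DataFrame({
            "iteration": it, "model": CONSENSUS, "id": ids[covered],
            "true": dataset.y[covered], "probability": cons_prob[covered],
            "predicted": cons_label[covered], "n_positive_votes": n_pos[covered],
        }))
        rows_pred.append(pd.concat(frames, ignore_index=True))

        for alg in ALGORITHMS:
            m = compute_metrics(
                confusion_from_predictions(dataset.y[covered], base_labels[alg][covered])
            )
            rows_metrics.append({"iteration": it, "model": alg, **m.as_dict()})
        m = compute_metrics(confusion_from_predictions(dataset.y[covered], cons_label[covered]))
        rows_metrics.append({"iteration": it, "model": CONSENSUS, **m.as_dict()})

    return CVResult(
        per_iteration=pd.DataFrame(rows_metrics),
        predictions=pd.concat(rows_pred, ignore_index=True),
        iterations=iterations,
        folds=folds,
        seed=seed,
    )


def loael_stratified_sensitivity(
    cv_result: CVResult, dataset: LabeledDataset, cutoff: float = 100.0
) -> pd.DataFrame:
    """Sensitivity on strong (LOAEL <= cutoff) vs weak (LOAEL > cutoff) positives.

    Computed per model from the pooled prediction log.  An empty stratum is
    reported as NaN (undefined), never as 0.
    """
    loael = pd.Series(dataset.loael, index=list(dataset.ids))
    preds = cv_result.predictions
    pos = preds[preds["true"] == 1].copy()
    pos["loael"] = pos["id"].map(loael)
    if pos["loael"].isna().any():
        bad = sorted(pos.loc[pos["loael"].isna(), "id"].unique())
        raise ValueError(f"positives without LOAEL values: {bad}")
    rows = []
    for model in MODEL_ORDER:
        sub = pos[pos["model"] == model]
        strong = sub[sub["loael"] <= cutoff]
        weak = sub[sub["loael"] > cutoff]
        rows.append({
            "model": model,
            "strong_sensitivity": strong["predicted"].mean() if len(strong) else float("nan"),
            "weak_sensitivity": weak["predicted"].mean() if len(weak) else float("nan"),
            "n_strong": len(strong),
            "n_weak": len(weak),
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ExternalResult:
    """Metrics and predictions from validating full-training-set models externally."""

    metrics: pd.DataFrame  # model x metric columns
    predictions: pd.DataFrame  # model, id, true, probability, predicted [, votes]


def external_validate(
    train: LabeledDataset, external: LabeledDataset, specs: Mapping[str, LearnerSpec]
) -> ExternalResult:
    """Fit the 7 models on the full training set and score the external set.

    External IDs must be disjoint from training IDs; overlaps are refused
    and named.
    """
    _check_specs(specs)
    overlap = sorted(set(train.ids) & set(external.ids))
    if overlap:
        raise ValueError(f"external chemicals overlap the training set: {overlap}")
    probs, labels = {}, {}
    for alg in ALGORITHMS:
        learner = fit(specs[alg], train)
        probs[alg] = learner.predict_proba(external.table)
        labels[alg] = classify(probs[alg])
    vote_matrix = np.column_stack([labels[alg] for alg in ALGORITHMS])
    n_pos, cons_label, cons_prob = consensus_predict(vote_matrix)

    frames, rows = [], []
    for alg in ALGORITHMS:
        frames.append(pd.DataFrame({
            "model": alg, "id": list(external.ids), "true": external.y,
            "probability": probs[alg], "predicted": labels[alg],
        }))
        m = compute_metrics(confusion_from_predictions(external.y, labels[alg]))
        rows.append({"model": alg, **m.as_dict()})
    frames.append(pd.DataFrame({
        "model": CONSENSUS, "id": list(external.ids), "true": external.y,
        "probability": cons_prob, "predicted": cons_label, "n_positive_votes": n_pos,
    }))
    m = compute_metrics(confusion_from_predictions(external.y, cons_label))
    rows.append({"model": CONSENSUS, **m.as_dict()})
    return ExternalResult(metrics=pd.DataFrame(rows), predictions=pd.concat(frames, ignore_index=True))
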