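"""Hyperparameter selection by inner repeated 5-fold cross-validation.

Tuning runs on a stratified 80% subset of the training chemicals drawn
once per run from the master seed, never on the data used for final
evaluation.  For each candidate setting, five repeats of a 5-fold CV are
run; the MCC of a repeat is computed on the repeat's pooled held-out
predictions, and the setting with the highest mean MCC over the five
repeats wins.  Ties break to the first-listed setting and are recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from reprotox._rng import derive_seed
from reprotox.dataio import LabeledDataset
from reprotox.evaluation import compute_metrics, confusion_from_predictions, make_folds
from reprotox.learners import ALGORITHMS, DEFAULT_GRIDS, LearnerSpec, classify, fit

__all__ = [
    "ParameterGrid",
    "TuningResult",
    "split_tuning_subset",
    "inner_cv_mcc",
    "grid_search",
    "tune_all",
]


@dataclass(frozen=True)
class ParameterGrid:
    """Candidate hyperparameter settings for one algorithm."""

    algorithm: str
    settings: tuple[dict, ...]

    def __post_init__(self) -> None:
        if not self.settings:
            raise ValueError("parameter grid must be non-empty")
        object.__setattr__(self, "settings", tuple(dict(s) for s in self.settings))


@dataclass(frozen=True)
class TuningResult:
    """Per-setting MCCs, the chosen setting, and the seed trail."""

    algorithm: str
    settings: tuple[dict, ...]
    mean_mccs: tuple[float, ...]
    repeat_mccs: tuple[tuple[float, ...], ...]
    chosen_index: int
    tied_indices: tuple[int, ...]
    seed: int

    @property
    def chosen(self) -> dict:
        return dict(self.settings[self.chosen_index])


def split_tuning_subset(
    dataset: LabeledDataset, fraction: float = 0.8, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Draw the tuning subset (stratified by class) and its complement.

    Returns (tuning subset, held-aside remainder); the split is by ID and
    asserted disjoint.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(derive_seed(seed, 41))
    take: list[int] = []
    for cls in np.unique(dataset.y):
        rows = np.flatnonzero(dataset.y == cls)
        rows = rows[rng.permutation(len(rows))]
        take.extend(rows[: int(round(fraction * len(rows)))])
    take_sorted = sorted(take)
    rest = sorted(set(range(dataset.n_chemicals)) - set(take_sorted))
    subset, remainder = dataset.take(take_sorted), dataset.take(rest)
    assert not set(subset.ids) & set(remainder.ids)
    return subset, remainder


def _repeat_mccs(
    spec: LearnerSpec, dataset: LabeledDataset, repeats: int, folds: int, seed: int,
    stratified: bool = False,
) -> list[float]:
    n = dataset.n_chemicals
    out = []
    for rep in range(repeats):
        plan = make_folds(
            n, folds=folds, seed=derive_seed(seed, 43, rep), stratified=stratified, y=dataset.y
        )
        pred = np.full(n, -1, dtype=int)
        for fold in range(folds):
            train_rows = np.flatnonzero(plan.assignment != fold)
            test_rows = np.flatnonzero(plan.assignment == fold)
            train_ds = dataset.take(train_rows)
            if len(np.unique(train_ds.y)) < 2:
                warnings.warn(f"single-class fold in inner CV (repeat {rep}, fold {fold})")
                continue
            learner = fit(spec, train_ds)
            pred[test_rows] = classify(learner.predict_proba(dataset.table.take(test_rows)))
        covered = pred >= 0
        m = compute_metrics(confusion_from_predictions(dataset.y[covered], pred[covered]))
        out.append(m.mcc)
    return out


def inner_cv_mcc(
    spec: LearnerSpec, dataset: LabeledDataset, repeats: int = 5, folds: int = 5, seed: int = 0
) -> float:
    """Mean MCC over repeated 5-fold CV; each repeat's MCC uses pooled predictions."""
    return float(np.mean(_repeat_mccs(spec, dataset, repeats, folds, seed)))


def grid_search(
    grid: ParameterGrid, dataset: LabeledDataset, seed: int = 0,
    repeats: int = 5, folds: int = 5,
) -> TuningResult:
    """Exhaustive inner-CV evaluation of the grid, maximizing mean MCC."""
    means, per_repeat = [], []
    for hp in grid.settings:
        spec = LearnerSpec(grid.algorithm, hp, seed=derive_seed(seed, 47))
        mccs = _repeat_mccs(spec, dataset, repeats, folds, seed)
        per_repeat.append(tuple(mccs))
        means.append(float(np.mean(mccs)))
    best = max(means)
    tied = tuple(i for i, m in enumerate(means) if m == best)
    return TuningResult(
        algorithm=grid.algorithm,
        settings=grid.settings,
        mean_mccs=tuple(means),
        repeat_mccs=tuple(per_repeat),
        chosen_index=tied[0],
        tied_indices=tied,
        seed=seed,
    )


def tune_all(
    dataset: LabeledDataset,
    grids: Mapping[str, Sequence[dict]] | None = None,
    seed: int = 0,
    fraction: float = 0.8,
    repeats: int = 5,
    folds: int = 5,
) -> tuple[dict[str, LearnerSpec], dict[str, TuningResult]]:
    """Tune all seven algorithms on the 80% tuning subset.

    Returns the chosen LearnerSpec per algorithm plus the full per-grid
    results for reporting.
    """
    grids = dict(grids) if grids is not None else DEFAULT_GRIDS
    subset, _ = split_tuning_subset(dataset, fraction=fraction, seed=seed)
    specs: dict[str, LearnerSpec] = {}
    results: dict[str, TuningResult] = {}
    for alg in ALGORITHMS:
        grid = ParameterGrid(alg, tuple(grids[alg]))
        res = grid_search(grid, subset, seed=derive_seed(seed, 53, ALGORITHMS.index(alg)),
                          repeats=repeats, folds=folds)
        results[alg] = res
        specs[alg] = LearnerSpec(alg, res.chosen, seed=derive_seed(seed, 59, ALGORITHMS.index(alg)))
    return specs, results
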