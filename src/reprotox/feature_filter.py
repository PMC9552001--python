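"""Three-stage descriptor selection.

Stage 1 removes sparse descriptors (zero for more than 90% of training
chemicals).  Stage 2 removes low-information descriptors by Shannon
entropy over 20 equal-width bins spanning the training min–max.  Stage 3
runs repeated 5-fold cross-validation fitting decision-tree, decision-
forest and random-forest models and keeps descriptors whose usage
frequency — normalized per algorithm by the maximum frequency and averaged
over the three algorithms — exceeds 0.2.

Stages 1 and 2 never see the labels, so they are invariant under label
permutation; stage 3 legitimately uses them.

Threshold conventions (documented in every FilterReport): the sparse
filter removes strictly above 0.90; the entropy filter removes strictly
below 2.5 (a descriptor at exactly 2.5 is kept); the importance filter
keeps strictly above 0.2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from reprotox._rng import derive_seed
from reprotox.dataio import LabeledDataset
from reprotox.evaluation import make_folds

__all__ = [
    "BinningSpec",
    "EntropyProfile",
    "ImportanceProfile",
    "FilterReport",
    "shannon_entropy",
    "entropy_profile",
    "drop_sparse_descriptors",
    "drop_low_entropy",
    "tree_frequency_importance",
    "select_by_importance",
    "filter_descriptors",
]

TREE_ALGORITHMS = ("DT", "DF", "RF")


@dataclass(frozen=True)
class BinningSpec:
    """Equal-width binning over [min, max] of the training values."""

    n_bins: int = 20

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be at least 2")


@dataclass(frozen=True)
class EntropyProfile:
    """Per-descriptor Shannon entropy (bits) and bin occupancies."""

    names: tuple[str, ...]
    entropies: np.ndarray
    occupancies: np.ndarray  # (n_descriptors, n_bins), rows sum to 1
    spec: BinningSpec


@dataclass(frozen=True)
class ImportanceProfile:
    """Tree-usage frequencies and derived importances per descriptor.

    importance[alg] = frequency[alg] / max-over-descriptors frequency[alg];
    overall importance = mean of the three per-algorithm importances.
    """

    names: tuple[str, ...]
    frequencies: Mapping[str, np.ndarray]  # algorithm -> counts per descriptor
    models_counted: Mapping[str, int]  # fitted model instances per algorithm

    @property
    def per_algorithm_importance(self) -> dict[str, np.ndarray]:
        out = {}
        for alg in TREE_ALGORITHMS:
            freq = np.asarray(self.frequencies[alg], dtype=float)
            mx = freq.max() if freq.size else 0.0
            out[alg] = freq / mx if mx > 0 else np.zeros_like(freq)
        return out

    @property
    def overall_importance(self) -> np.ndarray:
        per = self.per_algorithm_importance
        return np.mean([per[a] for a in TREE_ALGORITHMS], axis=0)


@dataclass(frozen=True)
class FilterReport:
    """Kept/removed descriptor names with the reason and thresholds used."""

    kept: tuple[str, ...]
    removed: dict[str, str] = field(default_factory=dict)  # name -> reason
    thresholds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.kept) & set(self.removed)
        if overlap:
            raise ValueError(f"descriptors both kept and removed: {sorted(overlap)}")


def shannon_entropy(values: Sequence[float], spec: BinningSpec = BinningSpec()) -> float:
    """Shannon entropy (bits) of one descriptor's value distribution.

    Values are assigned to ``spec.n_bins`` equal-width bins spanning
    [min, max]; the top bin is right-closed so the maximum lands in the
    last bin; 0·log2(0) is taken as 0.  A constant descriptor occupies a
    single bin and has entropy 0.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("entropy requires at least one finite value")
    lo, hi = v.min(), v.max()
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(v, bins=spec.n_bins, range=(lo, hi))
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def entropy_profile(dataset: LabeledDataset, spec: BinningSpec = BinningSpec()) -> EntropyProfile:
    table = dataset.table
    n_desc = table.n_descriptors
    ent = np.empty(n_desc)
    occ = np.zeros((n_desc, spec.n_bins))
    for j in range(n_desc):
        v = table.values[:, j]
        lo, hi = v.min(), v.max()
        if lo == hi:
            occ[j, 0] = 1.0
            ent[j] = 0.0
            continue
        counts, _ = np.histogram(v, bins=spec.n_bins, range=(lo, hi))
        p = counts / counts.sum()
        occ[j] = p
        nz = p[p > 0]
        ent[j] = float(-(nz * np.log2(nz)).sum())
    return EntropyProfile(table.descriptor_names, ent, occ, spec)


def drop_sparse_descriptors(
    dataset: LabeledDataset, zero_fraction_threshold: float = 0.90
) -> tuple[LabeledDataset, FilterReport]:
    """Remove descriptors that are zero for more than the threshold fraction.

    Strict inequality: a descriptor zero in exactly 90% of chemicals is kept.
    """
    table = dataset.table
    zero_frac = (table.values == 0).mean(axis=0)
    keep_mask = zero_frac <= zero_fraction_threshold
    if not keep_mask.any():
        raise ValueError("sparse filter removed every descriptor (degenerate input)")
    kept = [n for n, k in zip(table.descriptor_names, keep_mask) if k]
    removed = {n: "sparse" for n, k in zip(table.descriptor_names, keep_mask) if not k}
    report = FilterReport(tuple(kept), removed, {"zero_fraction_threshold": zero_fraction_threshold})
    return dataset.select_descriptors(kept), report


def drop_low_entropy(
    dataset: LabeledDataset,
    threshold: float = 2.5,
    spec: BinningSpec = BinningSpec(),
) -> tuple[LabeledDataset, FilterReport]:
    """Remove descriptors with Shannon entropy strictly below the threshold.

    A descriptor at exactly the threshold is kept (the boundary case is a
    documented convention; see FilterReport.thresholds).
    """
    profile = entropy_profile(dataset, spec)
    keep_mask = profile.entropies >= threshold
    if not keep_mask.any():
        raise ValueError("entropy filter removed every descriptor (degenerate input)")
    kept = [n for n, k in zip(profile.names, keep_mask) if k]
    removed = {n: "low_entropy" for n, k in zip(profile.names, keep_mask) if not k}
    report = FilterReport(
        tuple(kept), removed, {"entropy_threshold": threshold, "n_bins": spec.n_bins}
    )
    return dataset.select_descriptors(kept), report


def _descriptors_used_dt(tree, names: Sequence[str]) -> set[str]:
    feats = tree.tree_.feature
    return {names[f] for f in feats if f >= 0}


# Stage-3 model capacities.  The usage-frequency statistic discriminates only
# when a fitted model cannot afford to touch every descriptor: an unconstrained
# 100-tree forest splits on essentially all descriptors in every fit, driving
# every normalized importance to 1.  Compact models make descriptor choice a
# scarce resource, so frequency reflects genuine preference.
STAGE3_PARAMS = {
    "DT": {"max_depth": 10},
    "DF": {"n_trees": 5, "max_depth": 10},
    "RF": {"n_estimators": 10, "max_depth": 5},
}


def tree_frequency_importance(
    dataset: LabeledDataset,
    iterations: int = 500,
    folds: int = 5,
    seed: int = 0,
    stratified: bool = False,
) -> ImportanceProfile:
    """Descriptor-usage frequency over repeated-CV tree-model fits.

    For each iteration the chemicals are randomly divided into `folds`
    folds; on each 4-fold training part a decision tree, a decision forest
    and a random forest are fitted and the set of descriptors each fitted
    model actually splits on is recorded (counted once per model instance).
    """
    if iterations < 1:
        raise ValueError("iterations must be at least 1")
    from reprotox.learners import DecisionForestClassifier  # local import: avoid cycle
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.tree import DecisionTreeClassifier

    names = dataset.table.descriptor_names
    idx = {n: j for j, n in enumerate(names)}
    freq = {alg: np.zeros(len(names)) for alg in TREE_ALGORITHMS}
    counted = {alg: 0 for alg in TREE_ALGORITHMS}
    X, y = dataset.table.values, dataset.y

    for it in range(iterations):
        plan = make_folds(
            dataset.n_chemicals, folds=folds, seed=derive_seed(seed, 31, it),
            stratified=stratified, y=y,
        )
        for fold in range(folds):
            train_rows = np.flatnonzero(plan.assignment != fold)
            Xt, yt = X[train_rows], y[train_rows]
            if len(np.unique(yt)) < 2:
                warnings.warn(f"single-class training part at iteration {it}, fold {fold}; skipped")
                continue
            model_seed = derive_seed(seed, 37, it, fold)

            dt = DecisionTreeClassifier(random_state=model_seed, **STAGE3_PARAMS["DT"]).fit(Xt, yt)
            used = _descriptors_used_dt(dt, names)
            for n in used:
                freq["DT"][idx[n]] += 1
            counted["DT"] += 1

            df = DecisionForestClassifier(random_state=model_seed, **STAGE3_PARAMS["DF"]).fit(Xt, yt)
            for n in df.descriptors_used(names):
                freq["DF"][idx[n]] += 1
            counted["DF"] += 1

            rf = RandomForestClassifier(random_state=model_seed, **STAGE3_PARAMS["RF"]).fit(Xt, yt)
            used = set()
            for est in rf.estimators_:
                used |= _descriptors_used_dt(est, names)
            for n in used:
                freq["RF"][idx[n]] += 1
            counted["RF"] += 1

    return ImportanceProfile(names, freq, counted)


def select_by_importance(profile: ImportanceProfile, threshold: float = 0.2) -> FilterReport:
    """Keep descriptors with overall importance strictly greater than the threshold."""
    overall = profile.overall_importance
    # epsilon absorbs averaging round-off so "exactly at threshold" is removed
    cut = threshold + 1e-12
    kept = [n for n, v in zip(profile.names, overall) if v > cut]
    removed = {n: "low_importance" for n, v in zip(profile.names, overall) if v <= cut}
    return FilterReport(tuple(kept), removed, {"importance_threshold": threshold})


def filter_descriptors(
    dataset: LabeledDataset,
    zero_fraction_threshold: float = 0.90,
    entropy_threshold: float = 2.5,
    n_bins: int = 20,
    importance_threshold: float = 0.2,
    iterations: int = 500,
    folds: int = 5,
    seed: int = 0,
) -> tuple[LabeledDataset, FilterReport, ImportanceProfile]:
    """Run all three selection stages and merge the per-stage reports."""
    ds1, rep1 = drop_sparse_descriptors(dataset, zero_fraction_threshold)
    ds2, rep2 = drop_low_entropy(ds1, entropy_threshold, BinningSpec(n_bins))
    profile = tree_frequency_importance(ds2, iterations=iterations, folds=folds, seed=seed)
    rep3 = select_by_importance(profile, importance_threshold)
    if not rep3.kept:
        raise ValueError("importance filter removed every descriptor (degenerate input)")
    removed = {**rep1.removed, **rep2.removed, **rep3.removed}
    thresholds = {**rep1.thresholds, **rep2.thresholds, **rep3.thresholds,
                  "importance_iterations": iterations}
    report = FilterReport(rep3.kept, removed, thresholds)
    return ds2.select_descriptors(rep3.kept), report, profile
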