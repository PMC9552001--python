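"""The seven base classifiers behind one fit/predict-probability contract.

Algorithms: decision tree (DT), decision forest (DF), random forest (RF),
k-nearest neighbors (kNN), support vector machine (SVM), linear
discriminant analysis (LDA) and logistic regression (LR).  Six are
scikit-learn estimators; the decision forest — an ensemble of trees
constrained to pairwise-disjoint descriptor sets, combined by averaging
leaf-fraction probabilities — is implemented here.

Each trained learner carries an explicit probability contract for the
positive class:

==========  ===================================================
algorithm   positive-class probability
==========  ===================================================
DT          fraction of positive training chemicals in the leaf
DF, RF      mean of the member trees' leaf fractions
kNN         fraction of positives among the k neighbors
SVM         Platt sigmoid 1/(1+exp(A·f+B)) of the margin f, with
            A, B fitted by internal 5-fold cross-validation
LDA         two-class posterior (sigmoid of the discriminant)
LR          logistic sigmoid of the linear score
==========  ===================================================

Distance- and margin-based learners (kNN, SVM, LDA, LR) standardize the
descriptors using training mean/sd inside the fitted pipeline; tree-based
learners consume raw values.

The class decision rule everywhere: positive iff probability >= 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.calibration import CalibratedClassifierCV
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from reprotox._rng import derive_seed
from reprotox.dataio import DescriptorTable, LabeledDataset

__all__ = [
    "ALGORITHMS",
    "PROBABILITY_CONTRACTS",
    "DEFAULT_GRIDS",
    "QUICK_GRIDS",
    "LearnerSpec",
    "TrainedLearner",
    "DecisionForestClassifier",
    "fit",
    "fit_decision_forest",
    "predict_proba",
    "classify",
]

ALGORITHMS = ("DT", "DF", "RF", "kNN", "SVM", "LDA", "LR")

PROBABILITY_CONTRACTS = {
    "DT": "leaf_fraction",
    "DF": "tree_average",
    "RF": "tree_average",
    "kNN": "neighbor_fraction",
    "SVM": "platt_sigmoid",
    "LDA": "lda_posterior",
    "LR": "logistic_sigmoid",
}

_SCALED = {"kNN", "SVM", "LDA", "LR"}

# Conventional tuning grids; the choice of grids is a package default and is
# recorded verbatim in every tuning report.
DEFAULT_GRIDS: dict[str, list[dict]] = {
    "DT": [
        {"max_depth": d, "min_samples_leaf": m}
        for d in (3, 5, 10, None)
        for m in (1, 3, 5)
    ],
    "DF": [{"n_trees": t} for t in (3, 5, 7)],
    "RF": [
        {"n_estimators": n, "max_features": f}
        for n in (100, 500)
        for f in ("sqrt", 1 / 3)
    ],
    "kNN": [{"n_neighbors": k} for k in (3, 5, 7, 9)],
    "SVM": [{"C": c, "gamma": g} for c in (0.1, 1, 10) for g in ("scale", 0.01, 0.001)],
    "LDA": [{}],
    "LR": [{"C": c} for c in (0.01, 0.1, 1, 10)],
}

# Pruned grids for quick runs (smoke profiles); same shapes, fewer points.
QUICK_GRIDS: dict[str, list[dict]] = {
    "DT": [{"max_depth": d, "min_samples_leaf": m} for d in (5, None) for m in (1, 3)],
    "DF": [{"n_trees": t} for t in (3, 5)],
    "RF": [{"n_estimators": 100, "max_features": "sqrt"}],
    "kNN": [{"n_neighbors": k} for k in (3, 5, 7)],
    "SVM": [{"C": c, "gamma": "scale"} for c in (1, 10)],
    "LDA": [{}],
    "LR": [{"C": c} for c in (0.1, 1, 10)],
}


class DecisionForestClassifier(BaseEstimator, ClassifierMixin):
    """Ensemble of decision trees with pairwise-disjoint descriptor sets.

    Trees are grown sequentially; after each tree the descriptors it split
    on are withheld from all subsequent trees, so every descriptor
    contributes to at most one tree.  The ensemble probability is the mean
    of the member trees' leaf-fraction probabilities.

    If the descriptors are exhausted before ``n_trees`` trees are grown the
    forest stops early with a warning, provided at least two trees exist;
    otherwise fitting fails.
    """

    def __init__(self, n_trees: int = 5, max_depth=None, min_samples_leaf: int = 1,
                 random_state: int | None = None):
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state

    def fit(self, X, y):
        if self.n_trees < 2:
            raise ValueError("a decision forest needs at least 2 trees")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("single-class training data")
        n_features = X.shape[1]
        remaining = list(range(n_features))
        self.trees_: list[DecisionTreeClassifier] = []
        self.tree_feature_indices_: list[list[int]] = []
        base_seed = 0 if self.random_state is None else int(self.random_state)
        for t in range(self.n_trees):
            if not remaining:
                break
            tree = DecisionTreeClassifier(
                max_depth=self.max_depth,
                min_samples_leaf=self.min_samples_leaf,
                random_state=derive_seed(base_seed, 101, t),
            )
            tree.fit(X[:, remaining], y)
            used_local = sorted({f for f in tree.tree_.feature if f >= 0})
            self.trees_.append(tree)
            self.tree_feature_indices_.append(list(remaining))
            used_global = {remaining[f] for f in used_local}
            remaining = [j for j in remaining if j not in used_global]
            if not used_local:
                break  # a tree with no split blocks nothing; stop growing
        if len(self.trees_) < 2:
            raise ValueError("could not grow at least 2 trees with disjoint descriptors")
        if len(self.trees_) < self.n_trees:
            warnings.warn(
                f"decision forest stopped early: {len(self.trees_)} of "
                f"{self.n_trees} trees (descriptors exhausted)"
            )
        self.tree_used_indices_ = [
            sorted({cols[f] for f in tree.tree_.feature if f >= 0})
            for tree, cols in zip(self.trees_, self.tree_feature_indices_)
        ]
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        probs = np.mean(
            [t.predict_proba(X[:, cols]) for t, cols in zip(self.trees_, self.tree_feature_indices_)],
            axis=0,
        )
        return probs

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def descriptors_used(self, names: Sequence[str]) -> set[str]:
        """Names of descriptors split on by any member tree."""
        return {names[j] for used in self.tree_used_indices_ for j in used}


@dataclass(frozen=True)
class LearnerSpec:
    """One base classifier: algorithm name, hyperparameters, seed."""

    algorithm: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; expected one of {ALGORITHMS}")
        object.__setattr__(self, "hyperparameters", dict(self.hyperparameters))


@dataclass(frozen=True)
class TrainedLearner:
    """A fitted base classifier plus its probability contract."""

    spec: LearnerSpec
    model: object  # sklearn estimator or pipeline
    descriptor_names: tuple[str, ...]
    positive_index: int  # column of the positive class in predict_proba
    contract: str

    def predict_proba(self, table: DescriptorTable) -> np.ndarray:
        return predict_proba(self, table)

    def predict(self, table: DescriptorTable) -> np.ndarray:
        return classify(self.predict_proba(table))


def _build_estimator(spec: LearnerSpec):
    hp = dict(spec.hyperparameters)
    seed = spec.seed
    alg = spec.algorithm
    if alg == "DT":
        est = DecisionTreeClassifier(random_state=seed, **hp)
    elif alg == "DF":
        est = DecisionForestClassifier(random_state=seed, **hp)
    elif alg == "RF":
        est = RandomForestClassifier(random_state=seed, n_estimators=hp.pop("n_estimators", 100), **hp)
    elif alg == "kNN":
        est = KNeighborsClassifier(**hp)
    elif alg == "SVM":
        # Platt scaling of the SVM margin, A/B fitted by internal 5-fold CV
        svc = SVC(kernel=hp.pop("kernel", "rbf"), random_state=seed, **hp)
        est = CalibratedClassifierCV(svc, method="sigmoid", cv=5, ensemble=False)
    elif alg == "LDA":
        est = LinearDiscriminantAnalysis(**hp)
    elif alg == "LR":
        est = LogisticRegression(max_iter=2000, random_state=seed, **hp)
    else:  # pragma: no cover - guarded by LearnerSpec
        raise ValueError(alg)
    if alg in _SCALED:
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    return est


def fit(spec: LearnerSpec, dataset: LabeledDataset) -> TrainedLearner:
    """Fit one base classifier on a labeled dataset.

    Requires both classes present and a complete (finite) descriptor
    matrix; deterministic given ``spec.seed``.
    """
    X, y = dataset.table.values, dataset.y
    if not np.isfinite(X).all():
        raise ValueError("descriptor matrix contains missing or non-finite values")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("single-class training data: cannot fit a classifier")
    model = _build_estimator(spec).fit(X, y)
    fitted = model[-1] if isinstance(model, Pipeline) else model
    positive_index = int(np.flatnonzero(fitted.classes_ == 1)[0])
    return TrainedLearner(
        spec=spec,
        model=model,
        descriptor_names=dataset.table.descriptor_names,
        positive_index=positive_index,
        contract=PROBABILITY_CONTRACTS[spec.algorithm],
    )


def fit_decision_forest(
    dataset: LabeledDataset,
    n_trees: int = 5,
    tree_params: Mapping[str, object] | None = None,
    seed: int = 0,
) -> TrainedLearner:
    """Convenience constructor for the disjoint-descriptor decision forest."""
    hp = {"n_trees": n_trees, **(dict(tree_params) if tree_params else {})}
    return fit(LearnerSpec("DF", hp, seed), dataset)


def predict_proba(learner: TrainedLearner, table: DescriptorTable) -> np.ndarray:
    """Positive-class probability per chemical, under the learner's contract."""
    sub = table.select_descriptors(learner.descriptor_names)  # raises on missing columns
    proba = learner.model.predict_proba(sub.values)
    return np.clip(proba[:, learner.positive_index], 0.0, 1.0)


def classify(probabilities: np.ndarray) -> np.ndarray:
    """Label from probability: positive (1) iff probability >= 0.5.

    0.5 is the minimum probability at which a chemical is called positive,
    so the boundary value itself maps to positive.
    """
    p = np.asarray(probabilities, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    return (p >= 0.5).astype(int)
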