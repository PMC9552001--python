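"""Applicability-domain analysis by PCA-centroid distance.

The training descriptors are standardized (training mean/sd; zero-variance
descriptors dropped with a warning) and decomposed by principal component
analysis.  The smallest number of leading components whose cumulative
explained variance reaches the target (default 95%) is retained.  Every
chemical — training or external — is projected into that component space
and its Euclidean distance to the centroid of the training scores is
computed, together with the training-distance quantile of that distance
(e.g. "farther than 95% of training chemicals").  The training and
external distance distributions are compared with a two-sided
Mann–Whitney rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from reprotox.dataio import DescriptorTable

__all__ = [
    "PCModel",
    "DistanceReport",
    "DistanceComparison",
    "fit_pc_model",
    "project",
    "centroid_distance",
    "distance_report",
    "compare_distance_distributions",
]


@dataclass(frozen=True)
class PCModel:
    """Standardization statistics + principal-component basis of the training set."""

    descriptor_names: tuple[str, ...]
    center: np.ndarray
    scale: np.ndarray
    components: np.ndarray  # (n_all_components, n_descriptors)
    pca_mean: np.ndarray
    explained_variance_ratio: np.ndarray
    n_components: int
    variance_target: float
    centroid: np.ndarray  # training centroid in retained-component space
    train_distances: np.ndarray  # sorted training centroid distances

    @property
    def cumulative_variance(self) -> float:
        return float(self.explained_variance_ratio[: self.n_components].sum())


def fit_pc_model(
    train_table: DescriptorTable,
    variance_target: float = 0.95,
    n_components: int | None = None,
) -> PCModel:
    """Fit the PCA model of the training descriptor space.

    With ``n_components`` given, that many components are retained;
    otherwise the smallest count whose cumulative variance reaches
    ``variance_target``.
    """
    if train_table.n_chemicals < 2:
        raise ValueError("PCA requires at least 2 chemicals")
    X = train_table.values
    sd = X.std(axis=0, ddof=0)
    usable = sd > 0
    if not usable.all():
        dropped = [n for n, u in zip(train_table.descriptor_names, usable) if not u]
        warnings.warn(f"dropping zero-variance descriptors: {dropped}")
    names = tuple(n for n, u in zip(train_table.descriptor_names, usable) if u)
    if len(names) < 2:
        raise ValueError("fewer than 2 usable (non-constant) descriptors")
    center, scale = X[:, usable].mean(axis=0), sd[usable]
    Z = (X[:, usable] - center) / scale
    pca = PCA(n_components=min(Z.shape), svd_solver="full").fit(Z)
    evr = pca.explained_variance_ratio_
    if n_components is not None:
        if not (1 <= n_components <= len(evr)):
            raise ValueError(f"n_components must lie in [1, {len(evr)}]")
        k = int(n_components)
    else:
        if not (0.0 < variance_target <= 1.0):
            raise ValueError("variance_target must lie in (0, 1]")
        cum = np.cumsum(evr)
        # float-tolerant: variance_target=1.0 keeps all non-degenerate components
        k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
        k = min(k, len(evr))
    scores = pca.transform(Z)[:, :k]
    centroid = scores.mean(axis=0)
    dists = np.sqrt(((scores - centroid) ** 2).sum(axis=1))
    return PCModel(
        descriptor_names=names,
        center=center,
        scale=scale,
        components=pca.components_,
        pca_mean=pca.mean_,
        explained_variance_ratio=evr,
        n_components=k,
        variance_target=variance_target if n_components is None else float("nan"),
        centroid=centroid,
        train_distances=np.sort(dists),
    )


def project(model: PCModel, table: DescriptorTable) -> np.ndarray:
    """Scores of chemicals in the retained-component space."""
    sub = table.select_descriptors(model.descriptor_names)
    Z = (sub.values - model.center) / model.scale
    return (Z - model.pca_mean) @ model.components[: model.n_components].T


def centroid_distance(model: PCModel, table: DescriptorTable, group: str = "external") -> pd.DataFrame:
    """Euclidean distance of each chemical to the training-score centroid.

    The ``train_quantile`` column gives the fraction of training chemicals
    whose own centroid distance is <= the chemical's distance.
    """
    scores = project(model, table)
    d = np.sqrt(((scores - model.centroid) ** 2).sum(axis=1))
    # tolerance absorbs re-projection round-off so a training chemical's own
    # distance counts as <= its stored value
    d_tol = d + 1e-9 * (1.0 + d)
    quantile = np.searchsorted(model.train_distances, d_tol, side="right") / len(
        model.train_distances
    )
    return pd.DataFrame({
        "id": list(table.ids), "group": group, "distance": d, "train_quantile": quantile,
    })


@dataclass(frozen=True)
class DistanceReport:
    """Per-chemical centroid distances for the train and external groups."""

    table: pd.DataFrame  # columns: id, group, distance, train_quantile
    n_components: int


def distance_report(
    model: PCModel, train_table: DescriptorTable, external_table: DescriptorTable
) -> DistanceReport:
    frames = [
        centroid_distance(model, train_table, group="train"),
        centroid_distance(model, external_table, group="external"),
    ]
    return DistanceReport(pd.concat(frames, ignore_index=True), model.n_components)


@dataclass(frozen=True)
class DistanceComparison:
    statistic: float
    p_value: float  # NaN when a group is too small for the test
    median_train: float
    median_external: float

    @property
    def external_farther(self) -> bool:
        return self.median_external > self.median_train


def compare_distance_distributions(report: DistanceReport) -> DistanceComparison:
    """Two-sided Mann–Whitney test of external vs training centroid distances."""
    t = report.table
    train = t.loc[t["group"] == "train", "distance"].to_numpy()
    ext = t.loc[t["group"] == "external", "distance"].to_numpy()
    if len(train) == 0 or len(ext) == 0:
        raise ValueError("both groups must be non-empty")
    med_t, med_e = float(np.median(train)), float(np.median(ext))
    if min(len(train), len(ext)) < 3:
        warnings.warn("a group has fewer than 3 chemicals; descriptive output only")
        return DistanceComparison(float("nan"), float("nan"), med_t, med_e)
    res = stats.mannwhitneyu(ext, train, alternative="two-sided")
    return DistanceComparison(float(res.statistic), float(res.pvalue), med_t, med_e)
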