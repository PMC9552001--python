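"""Prediction-confidence analysis.

Confidence of a prediction with positive-class probability ``prob`` is
|prob − 0.5| / 0.5, a [0, 1] distance from the decision boundary that is
symmetric in the two classes (prob and 1 − prob give equal confidence).
Predictions are partitioned into 10 equal-width confidence bins,
[0, 0.1), ..., [0.9, 1.0] (top bin right-closed), and the per-bin accuracy
(optionally all seven metrics) is computed from the pooled prediction log.
The accuracy-vs-confidence trend is summarized by a count-weighted rank
correlation over the non-empty bins; sparsely populated bins are flagged
because their accuracies are statistically fragile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from reprotox.evaluation import CVResult, compute_metrics, confusion_from_predictions

__all__ = [
    "N_BINS",
    "ConfidenceProfile",
    "TrendSummary",
    "prediction_confidence",
    "confidence_records",
    "bin_by_confidence",
    "confidence_accuracy_trend",
]

N_BINS = 10


def prediction_confidence(prob):
    """Confidence |prob − 0.5| / 0.5 of a probability (scalar or array)."""
    p = np.asarray(prob, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    conf = np.abs(p - 0.5) / 0.5
    return float(conf) if np.isscalar(prob) or p.ndim == 0 else conf


def confidence_records(cv_result: CVResult, model: str) -> pd.DataFrame:
    """The pooled prediction log of one model, with a confidence column."""
    sub = cv_result.predictions
    sub = sub[sub["model"] == model].copy()
    if sub.empty:
        raise ValueError(f"no predictions for model {model!r}")
    sub["confidence"] = prediction_confidence(sub["probability"].to_numpy())
    return sub


@dataclass(frozen=True)
class ConfidenceProfile:
    """Per-bin counts and accuracy (empty bins: NaN, never 0)."""

    table: pd.DataFrame  # columns: bin, lower, upper, count, accuracy [+ metrics]
    total: int


def bin_by_confidence(records: pd.DataFrame, full_metrics: bool = False) -> ConfidenceProfile:
    """Partition predictions into the 10 confidence bins and score each bin.

    ``records`` needs columns ``confidence``, ``predicted`` and ``true``.
    """
    conf = records["confidence"].to_numpy(float)
    if ((conf < 0) | (conf > 1)).any():
        raise ValueError("confidence values must lie in [0, 1]")
    # [0,0.1), ..., [0.9,1.0]; clip puts confidence exactly 1.0 in the top bin
    bin_idx = np.clip((conf * N_BINS).astype(int), 0, N_BINS - 1)
    rows = []
    for b in range(N_BINS):
        mask = bin_idx == b
        count = int(mask.sum())
        row = {"bin": b, "lower": b / N_BINS, "upper": (b + 1) / N_BINS, "count": count}
        if count == 0:
            row["accuracy"] = float("nan")
        else:
            t = records["true"].to_numpy(int)[mask]
            p = records["predicted"].to_numpy(int)[mask]
            row["accuracy"] = float((t == p).mean())
            if full_metrics:
                row.update(compute_metrics(confusion_from_predictions(t, p)).as_dict())
        rows.append(row)
    table = pd.DataFrame(rows)
    assert int(table["count"].sum()) == len(records)
    return ConfidenceProfile(table, total=len(records))


@dataclass(frozen=True)
class TrendSummary:
    """Count-weighted rank correlation of bin accuracy vs bin index."""

    weighted_rank_correlation: float
    n_bins_used: int
    sparse_bins: tuple[int, ...]  # occupied bins holding < 1% of predictions


def _weighted_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    w = w / w.sum()
    mx, my = (w * x).sum(), (w * y).sum()
    cov = (w * (x - mx) * (y - my)).sum()
    vx = (w * (x - mx) ** 2).sum()
    vy = (w * (y - my) ** 2).sum()
    if vx <= 0 or vy <= 0:
        return 0.0
    return float(cov / np.sqrt(vx * vy))


def confidence_accuracy_trend(profile: ConfidenceProfile, sparse_fraction: float = 0.01) -> TrendSummary:
    """Does accuracy rise with confidence?  Weighted rank correlation summary.

    Bin accuracies are ranked (ties averaged) and correlated with bin index,
    each bin weighted by its prediction count; constant accuracy yields 0.
    """
    occ = profile.table[profile.table["count"] > 0]
    if len(occ) < 2:
        raise ValueError("trend analysis requires at least 2 non-empty bins")
    ranks = stats.rankdata(occ["accuracy"].to_numpy())
    corr = _weighted_pearson(
        occ["bin"].to_numpy(float), ranks, occ["count"].to_numpy(float)
    )
    sparse = tuple(
        int(b) for b, c in zip(occ["bin"], occ["count"]) if c < sparse_fraction * profile.total
    )
    return TrendSummary(corr, n_bins_used=len(occ), sparse_bins=sparse)
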