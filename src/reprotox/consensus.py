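"""Majority-vote consensus over the seven base classifiers.

A chemical is called positive when more than three of the seven models
vote positive (N⁺ > 3, i.e. at least 4 of 7).  The consensus probability
is a function of the vote count alone:

    N⁺ > 3:  p = 1 − (7 − N⁺) / 8      (0.625 … 1.0)
    N⁺ ≤ 3:  p = N⁺ / 6                (0 … 0.5)

Votes are base-model *labels* (probability >= 0.5), never averaged
probabilities.  The vote count is hard-coded to seven models; subsets are
refused rather than generalized.

Note the printed rule has a boundary quirk at N⁺ = 3: the label is
negative while the probability is exactly 0.5 (confidence 0).  It is
implemented exactly as stated and flagged in reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["N_MODELS", "ConsensusPrediction", "consensus_probability", "consensus_vote",
           "consensus_predict"]

N_MODELS = 7
_VOTE_THRESHOLD = 3  # positive iff N+ > 3


@dataclass(frozen=True)
class ConsensusPrediction:
    """Vote count N⁺, consensus label, and consensus probability."""

    n_positive_votes: int
    label: int  # 1 positive, 0 negative
    probability: float


def consensus_probability(n_positive: int) -> float:
    """Consensus positive-class probability from the vote count N⁺ ∈ {0..7}."""
    n = int(n_positive)
    if n != n_positive or not (0 <= n <= N_MODELS):
        raise ValueError(f"N+ must be an integer in [0, {N_MODELS}], got {n_positive!r}")
    if n > _VOTE_THRESHOLD:
        return 1.0 - (N_MODELS - n) / 8.0
    return n / 6.0


def consensus_vote(labels: Sequence[int]) -> ConsensusPrediction:
    """Combine exactly seven base-model labels into a consensus prediction."""
    votes = np.asarray(labels, dtype=int)
    if votes.shape != (N_MODELS,):
        raise ValueError(f"consensus requires exactly {N_MODELS} votes, got {votes.shape}")
    if not np.isin(votes, (0, 1)).all():
        raise ValueError("votes must be 0 or 1")
    n_pos = int(votes.sum())
    return ConsensusPrediction(
        n_positive_votes=n_pos,
        label=int(n_pos > _VOTE_THRESHOLD),
        probability=consensus_probability(n_pos),
    )


def consensus_predict(label_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized consensus over an (n_chemicals, 7) matrix of base labels.

    Returns (vote counts, labels, probabilities).
    """
    votes = np.asarray(label_matrix, dtype=int)
    if votes.ndim != 2 or votes.shape[1] != N_MODELS:
        raise ValueError(f"expected an (n, {N_MODELS}) label matrix, got {votes.shape}")
    n_pos = votes.sum(axis=1)
    labels = (n_pos > _VOTE_THRESHOLD).astype(int)
    probs = np.where(n_pos > _VOTE_THRESHOLD, 1.0 - (N_MODELS - n_pos) / 8.0, n_pos / 6.0)
    return n_pos, labels, probs
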