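"""Synthetic descriptor-study generator.

Emulates the statistical structure of a Mold2-style QSAR study without any
chemistry: a training table of chemicals x numeric descriptors with
heterogeneous scales, a mixture of continuous and non-negative count-like
columns, a block of sparse (mostly-zero) descriptors, a block of
class-informative descriptors, binary toxicity labels driven by a latent
Gaussian severity score, LOAEL doses (positives only) spanning several
orders of magnitude and anti-correlated with severity, and an external
validation set whose informative-descriptor means are shifted away from
the training centroid (covariate shift).

Defaults mirror the composition of the study this pipeline was designed
around: 275 training chemicals (94 positive / 181 negative), 777
descriptors, a 29-chemical external set (18 positive / 11 negative) and
LOAELs spanning four orders of magnitude.  The generator makes no claim
about real descriptor covariance; it exists so that every downstream stage
(zero filter, entropy binning, importance selection, learners, consensus,
confidence, applicability domain) is exercised on data with the right
shape and difficulty dials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from reprotox._rng import derive_rng
from reprotox.dataio import DescriptorTable, LabeledDataset

__all__ = [
    "SyntheticConfig",
    "GeneratedStudy",
    "default_study_config",
    "generate_training_set",
    "generate_external_set",
    "assign_loael",
    "generate_study",
]

# fixed sub-stream keys off the master seed
_K_ROLES, _K_PARAMS, _K_TRAIN, _K_EXTERNAL, _K_LOAEL = 1, 2, 3, 4, 5
_K_LABELS_TRAIN, _K_LABELS_EXT, _K_LATENT_TRAIN, _K_LATENT_EXT = 6, 7, 8, 9


@dataclass(frozen=True)
class SyntheticConfig:
    """Dials of the generative model.

    effect_size is the standardized mean shift of informative descriptors
    between classes; shift_magnitude the standardized mean shift applied to
    the whole external set; loael_anticorrelation the target rank
    correlation between LOAEL and the latent severity score (−1 reverses
    ranks exactly).
    """

    n_train: int = 275
    n_external: int = 29
    n_descriptors: int = 777
    n_informative: int = 34
    n_sparse: int = 272
    positive_fraction: float = 94 / 275
    external_positive_fraction: Optional[float] = None
    effect_size: float = 1.0
    sparse_zero_fraction: float = 0.95
    loael_log10_range: tuple[float, float] = (0.0, 4.0)
    loael_anticorrelation: float = -0.8
    shift_magnitude: float = 0.0
    exact_counts: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_train", "n_external", "n_descriptors"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_informative < 0 or self.n_sparse < 0:
            raise ValueError("n_informative and n_sparse must be non-negative")
        if self.n_informative + self.n_sparse > self.n_descriptors:
            raise ValueError("n_informative + n_sparse exceeds n_descriptors")
        for frac in (self.positive_fraction,) + (
            (self.external_positive_fraction,) if self.external_positive_fraction is not None else ()
        ):
            if not (0.0 < frac < 1.0):
                raise ValueError("positive fractions must lie strictly in (0, 1)")
        lo, hi = self.loael_log10_range
        if not lo < hi:
            raise ValueError("loael_log10_range bounds must be ordered")
        if not (0.0 <= self.sparse_zero_fraction < 1.0):
            raise ValueError("sparse_zero_fraction must lie in [0, 1)")
        if not (-1.0 <= self.loael_anticorrelation <= 0.0):
            raise ValueError("loael_anticorrelation must lie in [-1, 0]")


@dataclass(frozen=True)
class GeneratedStudy:
    """Train + external datasets with the generator's ground truth."""

    train: LabeledDataset
    external: LabeledDataset
    informative_names: tuple[str, ...]
    train_latent: np.ndarray
    external_latent: np.ndarray


def default_study_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """The study-shaped configuration: 275 train / 29 external chemicals,
    18 external positives, and a mild covariate shift (0.5 sd) of the
    external set away from the training centroid."""
    base = SyntheticConfig(seed=seed, external_positive_fraction=18 / 29, shift_magnitude=0.5)
    return replace(base, **overrides) if overrides else base


# ---------------------------------------------------------------------------
# column plan


@dataclass(frozen=True)
class _ColumnPlan:
    names: tuple[str, ...]
    informative: np.ndarray  # column indices
    sparse: np.ndarray
    count_like: np.ndarray
    continuous: np.ndarray
    loc: np.ndarray  # per-column location
    scale: np.ndarray  # per-column scale (heterogeneous)
    lam: np.ndarray  # Poisson rate for count-like columns (NaN elsewhere)


def _plan_columns(config: SyntheticConfig) -> _ColumnPlan:
    d = config.n_descriptors
    names = tuple(f"D{j + 1:04d}" for j in range(d))
    roles_rng = derive_rng(config.seed, _K_ROLES)
    order = roles_rng.permutation(d)
    informative = np.sort(order[: config.n_informative])
    sparse = np.sort(order[config.n_informative : config.n_informative + config.n_sparse])
    rest = np.sort(order[config.n_informative + config.n_sparse :])
    # half the leftover noise columns are count-like (atom/bond-count style),
    # half continuous with log-normal scale variation
    count_like = rest[roles_rng.random(len(rest)) < 0.5]
    continuous = np.setdiff1d(rest, count_like)

    params_rng = derive_rng(config.seed, _K_PARAMS)
    scale = params_rng.lognormal(mean=0.0, sigma=1.2, size=d)
    loc = params_rng.normal(0.0, 1.5, size=d) * scale
    lam = np.full(d, np.nan)
    # log-uniform rates: a realistic share of count columns is near-constant,
    # which is what the entropy filter exists to remove
    lam[count_like] = 10.0 ** params_rng.uniform(
        math.log10(0.3), math.log10(30.0), size=len(count_like)
    )
    # informative columns live on the standardized scale so effect_size is a
    # standardized shift before the per-column affine map
    return _ColumnPlan(names, informative, sparse, count_like, continuous, loc, scale, lam)


def _draw_labels(n: int, fraction: float, exact: bool, rng: np.random.Generator) -> np.ndarray:
    if exact:
        n_pos = int(round(n * fraction))
        n_pos = min(max(n_pos, 1), n - 1)
        y = np.zeros(n, dtype=int)
        y[rng.permutation(n)[:n_pos]] = 1
        return y
    return (rng.random(n) < fraction).astype(int)


def _draw_latent(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Latent toxicity severity: positives ~ N(1, 0.35) clipped away from 0."""
    t = np.zeros(len(y))
    n_pos = int(y.sum())
    if n_pos:
        t[y == 1] = np.clip(rng.normal(1.0, 0.35, size=n_pos), 0.05, None)
    return t


def _fill_matrix(
    plan: _ColumnPlan,
    config: SyntheticConfig,
    y: np.ndarray,
    latent: np.ndarray,
    rng: np.random.Generator,
    shift: float,
) -> np.ndarray:
    n, d = len(y), config.n_descriptors
    X = np.empty((n, d))

    for j in plan.continuous:
        X[:, j] = plan.loc[j] + plan.scale[j] * rng.normal(size=n)
    for j in plan.count_like:
        X[:, j] = rng.poisson(plan.lam[j], size=n).astype(float)
    for j in plan.sparse:
        col = np.zeros(n)
        n_zero = min(n, math.ceil(config.sparse_zero_fraction * n))
        nonzero = rng.permutation(n)[n_zero:]
        col[nonzero] = rng.lognormal(0.0, 1.0, size=len(nonzero))
        X[:, j] = col
    for j in plan.informative:
        z = rng.normal(size=n) + config.effect_size * latent + shift
        X[:, j] = plan.loc[j] + plan.scale[j] * z
    return X


def generate_training_set(config: SyntheticConfig) -> LabeledDataset:
    """Training table with labels and LOAELs under the configured dials."""
    plan = _plan_columns(config)
    label_rng = derive_rng(config.seed, _K_LABELS_TRAIN)
    y = _draw_labels(config.n_train, config.positive_fraction, config.exact_counts, label_rng)
    latent = _draw_latent(y, derive_rng(config.seed, _K_LATENT_TRAIN))
    X = _fill_matrix(plan, config, y, latent, derive_rng(config.seed, _K_TRAIN), shift=0.0)
    ids = tuple(f"TRN-{i + 1:04d}" for i in range(config.n_train))
    dataset = LabeledDataset(
        DescriptorTable(ids, plan.names, X), y, np.full(config.n_train, np.nan)
    )
    return assign_loael(dataset, config, latent)


def assign_loael(
    dataset: LabeledDataset, config: SyntheticConfig, latent: np.ndarray
) -> LabeledDataset:
    """Give every positive a LOAEL anti-correlated with its latent severity.

    Log10 doses are evenly spaced over ``loael_log10_range`` (so the spread
    is exactly the configured range) and assigned by the rank of a Gaussian
    copula mixing −severity with noise; at anticorrelation −1 the LOAEL
    rank order exactly reverses the severity rank order.
    """
    latent = np.asarray(latent, dtype=float)
    if latent.shape != (dataset.n_chemicals,):
        raise ValueError("latent scores not aligned with dataset")
    pos = np.flatnonzero(dataset.y == 1)
    loael = np.full(dataset.n_chemicals, np.nan)
    if len(pos) == 0:
        return LabeledDataset(dataset.table, dataset.y, loael)
    lo, hi = config.loael_log10_range
    n_pos = len(pos)
    log_doses = np.linspace(lo, hi, n_pos) if n_pos > 1 else np.array([(lo + hi) / 2])

    c = -config.loael_anticorrelation  # mixing weight in [0, 1]
    t = latent[pos]
    t_std = (t - t.mean()) / (t.std() if t.std() > 0 else 1.0)
    rng = derive_rng(config.seed, _K_LOAEL)
    score = c * (-t_std) + math.sqrt(max(0.0, 1.0 - c * c)) * rng.normal(size=n_pos)
    # lowest score (highest severity) gets the lowest dose
    ranks = np.argsort(np.argsort(score, kind="stable"), kind="stable")
    loael[pos] = 10.0 ** log_doses[ranks]
    return LabeledDataset(dataset.table, dataset.y, loael)


def generate_external_set(config: SyntheticConfig, train: LabeledDataset) -> LabeledDataset:
    """External set from the same generative family, shifted by shift_magnitude.

    The standardized means of the informative descriptors are displaced by
    ``shift_magnitude`` for every external chemical, so with a positive
    shift the set sits away from the training centroid in descriptor space.
    """
    plan = _plan_columns(config)
    fraction = (
        config.external_positive_fraction
        if config.external_positive_fraction is not None
        else config.positive_fraction
    )
    label_rng = derive_rng(config.seed, _K_LABELS_EXT)
    y = _draw_labels(config.n_external, fraction, config.exact_counts, label_rng)
    latent = _draw_latent(y, derive_rng(config.seed, _K_LATENT_EXT))
    X = _fill_matrix(
        plan, config, y, latent, derive_rng(config.seed, _K_EXTERNAL), shift=config.shift_magnitude
    )
    ids = tuple(f"EXT-{i + 1:04d}" for i in range(config.n_external))
    clash = set(ids) & set(train.ids)
    if clash:
        raise ValueError(f"external IDs collide with training IDs: {sorted(clash)}")
    dataset = LabeledDataset(
        DescriptorTable(ids, plan.names, X), y, np.full(config.n_external, np.nan)
    )
    return assign_loael(dataset, config, latent)


def generate_study(config: SyntheticConfig) -> GeneratedStudy:
    """Train + external sets plus ground truth (informative names, latent scores)."""
    plan = _plan_columns(config)
    train = generate_training_set(config)
    external = generate_external_set(config, train)
    train_latent = _draw_latent(train.y, derive_rng(config.seed, _K_LATENT_TRAIN))
    external_latent = _draw_latent(external.y, derive_rng(config.seed, _K_LATENT_EXT))
    return GeneratedStudy(
        train=train,
        external=external,
        informative_names=tuple(plan.names[j] for j in plan.informative),
        train_latent=train_latent,
        external_latent=external_latent,
    )
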