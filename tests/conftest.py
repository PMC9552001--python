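import numpy as np
import pytest

from reprotox.dataio import DescriptorTable, LabeledDataset
from reprotox.evaluation import run_repeated_cv
from reprotox.feature_filter import drop_low_entropy, drop_sparse_descriptors
from reprotox.learners import ALGORITHMS, LearnerSpec
from reprotox.synthetic_data import default_study_config, generate_study


def make_dataset(X, y, loael=None, prefix="C"):
    """Wrap raw arrays into a LabeledDataset with generated IDs/names."""
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    table = DescriptorTable(
        tuple(f"{prefix}{i:03d}" for i in range(n)),
        tuple(f"d{j:02d}" for j in range(d)),
        X,
    )
    if loael is None:
        loael = np.full(n, np.nan)
    return LabeledDataset(table, np.asarray(y, dtype=int), np.asarray(loael, dtype=float))


def separable_dataset(n_per_class=12, n_descriptors=4, gap=8.0, seed=0):
    """Two well-separated Gaussian clusters; every descriptor is informative."""
    rng = np.random.default_rng(seed)
    X0 = rng.normal(0.0, 1.0, size=(n_per_class, n_descriptors))
    X1 = rng.normal(gap, 1.0, size=(n_per_class, n_descriptors))
    X = np.vstack([X0, X1])
    y = np.array([0] * n_per_class + [1] * n_per_class)
    return make_dataset(X, y)


def base_specs(seed=0):
    """Untuned default specs for all seven algorithms."""
    return {alg: LearnerSpec(alg, {}, seed) for alg in ALGORITHMS}


@pytest.fixture(scope="session")
def strong_study():
    """A small, strongly separable synthetic study with a shifted external set."""
    cfg = default_study_config(
        seed=11, n_train=120, n_external=40, n_descriptors=60, n_informative=10,
        n_sparse=10, effect_size=3.0, shift_magnitude=2.0,
        external_positive_fraction=0.5,
    )
    return generate_study(cfg)


@pytest.fixture(scope="session")
def strong_filtered(strong_study):
    """Training set after the two label-blind filter stages."""
    ds, _ = drop_sparse_descriptors(strong_study.train)
    ds, _ = drop_low_entropy(ds)
    return ds


@pytest.fixture(scope="session")
def small_cv(strong_filtered):
    """A 2-iteration repeated CV of all 8 models, reused across test modules."""
    return run_repeated_cv(strong_filtered, base_specs(seed=5), iterations=2, seed=5)
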