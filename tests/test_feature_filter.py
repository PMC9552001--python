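import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reprotox.feature_filter import (
    BinningSpec,
    ImportanceProfile,
    drop_low_entropy,
    drop_sparse_descriptors,
    entropy_profile,
    filter_descriptors,
    select_by_importance,
    shannon_entropy,
    tree_frequency_importance,
)
from reprotox.synthetic_data import default_study_config, generate_study

from conftest import make_dataset


def brute_entropy(values, n_bins=20):
    """Independent entropy oracle: explicit bin assignment and plain sum."""
    values = list(values)
    lo, hi = min(values), max(values)
    if lo == hi:
        return 0.0
    width = (hi - lo) / n_bins
    counts = [0] * n_bins
    for v in values:
        b = min(int((v - lo) / width), n_bins - 1)  # top bin right-closed
        counts[b] += 1
    total = sum(counts)
    return -sum((c / total) * math.log2(c / total) for c in counts if c)


class TestShannonEntropy:
    def test_constant_descriptor_is_zero(self):
        assert shannon_entropy([3.0] * 50) == 0.0

    def test_uniform_over_20_bins_is_log2_20(self):
        # one value per bin center
        values = [i + 0.5 for i in range(20)]
        assert shannon_entropy(values) == pytest.approx(math.log2(20), abs=1e-12)

    def test_known_occupancies(self):
        # occupancies (0.5, 0.25, 0.25) over 20 bins -> H = 1.5 bits
        values = [0.0, 0.0, 1.5, 2.5]
        assert shannon_entropy(values) == pytest.approx(1.5, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            shannon_entropy([])

    def test_n_bins_below_two_rejected(self):
        with pytest.raises(ValueError):
            BinningSpec(n_bins=1)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=80),
           st.integers(2, 32))
    def test_entropy_bounds_property(self, values, n_bins):
        h = shannon_entropy(values, BinningSpec(n_bins))
        assert 0.0 <= h <= math.log2(n_bins) + 1e-9

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=60))
    def test_matches_brute_force_oracle(self, values):
        assert shannon_entropy(values) == pytest.approx(brute_entropy(values), abs=1e-9)


class TestSparseFilter:
    def _dataset_with_zero_counts(self, zero_counts, n=100):
        rng = np.random.default_rng(0)
        cols = []
        for z in zero_counts:
            col = rng.lognormal(size=n)
            col[:z] = 0.0
            cols.append(col)
        X = np.column_stack(cols)
        y = rng.integers(0, 2, size=n)
        return make_dataset(X, y)

    def test_strict_boundary_at_90_percent(self):
        ds = self._dataset_with_zero_counts([91, 90, 0])
        filtered, report = drop_sparse_descriptors(ds)
        assert report.removed == {"d00": "sparse"}
        assert filtered.table.descriptor_names == ("d01", "d02")

    def test_all_removed_is_an_error(self):
        ds = self._dataset_with_zero_counts([95, 99])
        with pytest.raises(ValueError, match="every descriptor"):
            drop_sparse_descriptors(ds)


class TestEntropyFilter:
    def test_partition_matches_oracle(self):
        rng = np.random.default_rng(4)
        # mix of constant, few-valued and spread-out descriptors straddling 2.5
        cols = [np.full(100, 7.0),
                rng.integers(0, 3, 100).astype(float),
                rng.integers(0, 8, 100).astype(float),
                rng.normal(size=100),
                rng.uniform(size=100)]
        ds = make_dataset(np.column_stack(cols), rng.integers(0, 2, 100))
        filtered, report = drop_low_entropy(ds)
        for j, name in enumerate(ds.table.descriptor_names):
            h = brute_entropy(ds.table.values[:, j])
            if h < 2.5:
                assert report.removed.get(name) == "low_entropy"
            else:
                assert name in report.kept

    def test_constant_removed_uniform_kept(self):
        rng = np.random.default_rng(1)
        ds = make_dataset(
            np.column_stack([np.full(60, 2.0), rng.uniform(size=60)]),
            rng.integers(0, 2, 60),
        )
        _, report = drop_low_entropy(ds)
        assert report.removed == {"d00": "low_entropy"}

    def test_exactly_at_threshold_is_kept(self):
        # crafted occupancies (1/4, 1/4, 1/8, 1/8, 1/8, 1/8) -> H = 2.5 exactly
        reps = [4, 4, 2, 2, 2, 2]
        values = np.repeat(np.linspace(0, 19, 6), reps)
        h = shannon_entropy(values)
        assert h == pytest.approx(2.5, abs=1e-12)
        rng = np.random.default_rng(2)
        ds = make_dataset(values.reshape(-1, 1), rng.integers(0, 2, len(values)))
        _, report = drop_low_entropy(ds)
        assert report.kept == ("d00",)

    def test_profile_occupancies_sum_to_one(self, strong_filtered):
        prof = entropy_profile(strong_filtered)
        np.testing.assert_allclose(prof.occupancies.sum(axis=1), 1.0, atol=1e-12)


class TestLabelBlindness:
    def test_stages_one_and_two_ignore_labels(self, strong_study):
        """Sparse and entropy filters give identical output for permuted labels."""
        train = strong_study.train
        rng = np.random.default_rng(99)
        shuffled = train.__class__(train.table, rng.permutation(train.y),
                                   train.loael)
        a1, ra = drop_sparse_descriptors(train)
        b1, rb = drop_sparse_descriptors(shuffled)
        assert ra.kept == rb.kept
        a2, ra2 = drop_low_entropy(a1)
        b2, rb2 = drop_low_entropy(b1)
        assert ra2.kept == rb2.kept
        np.testing.assert_array_equal(a2.table.values, b2.table.values)


class TestImportance:
    def test_single_iteration_counts_five_models_per_algorithm(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 6))
        y = (X[:, 0] > 0).astype(int)
        ds = make_dataset(X, y)
        profile = tree_frequency_importance(ds, iterations=1, folds=5, seed=0)
        assert profile.models_counted == {"DT": 5, "DF": 5, "RF": 5}
        for alg in ("DT", "DF", "RF"):
            assert profile.frequencies[alg].max() <= 5

    def test_importance_arithmetic(self):
        # descriptor used by every DT, half the DF, no RF -> overall 0.5
        profile = ImportanceProfile(
            names=("a", "b"),
            frequencies={"DT": np.array([10, 10]), "DF": np.array([5, 10]),
                         "RF": np.array([0, 10])},
            models_counted={"DT": 10, "DF": 10, "RF": 10},
        )
        np.testing.assert_allclose(profile.overall_importance,
                                   [(1 + 0.5 + 0) / 3, 1.0])

    def test_selection_boundary_is_strict(self):
        profile = ImportanceProfile(
            names=("exact", "above", "top"),
            frequencies={alg: np.array([20, 21, 100]) for alg in ("DT", "DF", "RF")},
            models_counted={alg: 100 for alg in ("DT", "DF", "RF")},
        )
        report = select_by_importance(profile, threshold=0.2)
        assert "exact" in report.removed  # importance 0.200 exactly
        assert "above" in report.kept  # importance 0.21
        assert "top" in report.kept

    def test_iterations_below_one_rejected(self, strong_filtered):
        with pytest.raises(ValueError):
            tree_frequency_importance(strong_filtered, iterations=0)

    def test_informative_descriptors_survive_full_pipeline(self, strong_study):
        filtered, report, profile = filter_descriptors(
            strong_study.train, iterations=5, seed=2
        )
        kept = set(report.kept)
        informative = set(strong_study.informative_names)
        assert informative <= kept
        # noise importance sits clearly below informative importance
        overall = dict(zip(profile.names, profile.overall_importance))
        inf_scores = [overall[n] for n in informative if n in overall]
        noise_scores = [v for n, v in overall.items() if n not in informative]
        assert np.mean(inf_scores) > np.mean(noise_scores)


def test_pipeline_descriptor_count_never_increases(strong_study):
    train = strong_study.train
    ds1, _ = drop_sparse_descriptors(train)
    ds2, _ = drop_low_entropy(ds1)
    filtered, _, _ = filter_descriptors(train, iterations=3, seed=0)
    counts = [train.table.n_descriptors, ds1.table.n_descriptors,
              ds2.table.n_descriptors, filtered.table.n_descriptors]
    assert counts == sorted(counts, reverse=True)
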