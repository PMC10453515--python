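"""Elimination-cascade logic: splits, relabelling, level flow, invariants."""

import numpy as np
import pandas as pd
import pytest

from conftest import random_feature_dataset
from nestout.features import FeatureDataset
from nestout.nestbc import (
    OUTLIER_LABEL,
    BaseClassifierConfig,
    NestedBinaryClassifier,
    relabel_binary,
    run_nested,
    split_train_test,
)

ORACLE = BaseClassifierConfig(algorithm="oracle")


class _AlwaysZero:
    """Degenerate base: recognises nothing at any level."""

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.zeros(len(X), dtype=int)


ALWAYS_ZERO = BaseClassifierConfig(
    algorithm="cart", estimator_factory=lambda seed: _AlwaysZero()
)


def _dataset(labels, seed=0, n_features=4):
    labels = np.array(labels, dtype=object)
    rng = np.random.default_rng(seed)
    features = pd.DataFrame(
        rng.normal(size=(len(labels), n_features)),
        columns=[f"f{j}" for j in range(n_features)],
    )
    return FeatureDataset(features, pd.Series(labels, dtype=object))


class TestSplit:
    def test_70_30_sizes(self):
        ds = _dataset(["a"] * 100)
        train, test = split_train_test(ds, 0.7, seed=0)
        assert (len(train), len(test)) == (70, 30)

    def test_same_seed_same_partition(self):
        ds = _dataset(["a", "b"] * 25)
        a1, b1 = split_train_test(ds, 0.7, seed=5)
        a2, b2 = split_train_test(ds, 0.7, seed=5)
        assert a1.index.equals(a2.index) and b1.index.equals(b2.index)

    def test_round_half_away(self):
        ds = _dataset(["a"] * 7)
        train, test = split_train_test(ds, 0.5, seed=1)
        assert (len(train), len(test)) == (4, 3)

    def test_partition_is_disjoint_and_complete(self):
        ds = _dataset(["a"] * 31)
        train, test = split_train_test(ds, 0.6, seed=2)
        union = train.index.union(test.index)
        assert len(train.index.intersection(test.index)) == 0
        assert union.sort_values().equals(ds.index)

    def test_too_small_is_error(self):
        with pytest.raises(ValueError):
            split_train_test(_dataset(["a"]), 0.7, seed=0)


class TestRelabel:
    def test_definition(self):
        ds = _dataset(["a", "b", "a", "c"])
        assert list(relabel_binary(ds, "a").labels) == [1, 0, 1, 0]

    def test_absent_activity_all_zero(self):
        ds = _dataset(["a", "b"])
        assert list(relabel_binary(ds, "z").labels) == [0, 0]

    def test_positive_count_matches_label_count(self):
        rng = np.random.default_rng(0)
        ds = random_feature_dataset(rng, 50, ["a", "b", "c"])
        out = relabel_binary(ds, "b")
        assert int(out.labels.sum()) == int((ds.labels == "b").sum())
        assert list(ds.labels.unique()) != [0, 1]  # original untouched


class TestRunNested:
    def test_one_level_per_activity(self):
        rng = np.random.default_rng(1)
        train = random_feature_dataset(rng, 40, ["a", "b", "c", "d"], min_per_class=3)
        test = random_feature_dataset(rng, 20, ["a", "b", "c", "d"])
        result = run_nested(train, test, ["a", "b", "c", "d"], ORACLE, seed=0)
        assert len(result.levels) == 4

    def test_oracle_elimination_example(self):
        train = _dataset(["a", "a", "b", "b"])
        test = _dataset(["a", "a", "b", "c"], seed=9)
        result = run_nested(train, test, ["a", "b"], ORACLE, seed=0)
        counts = result.assignment.value_counts().to_dict()
        assert counts == {"a": 2, "b": 1, OUTLIER_LABEL: 1}
        assert list(test.labels.loc[result.outlier_indices]) == ["c"]

    def test_always_zero_base_leaves_everything_as_outlier(self):
        train = _dataset(["a", "a", "b", "b"])
        test = _dataset(["a", "b", "a", "b"], seed=3)
        result = run_nested(train, test, ["a", "b"], ALWAYS_ZERO, seed=0)
        assert result.n_outliers == len(test)
        assert set(result.assignment) == {OUTLIER_LABEL}

    def test_missing_training_activity_is_error(self):
        train = _dataset(["a", "a", "b", "b"])
        test = _dataset(["a", "b"], seed=3)
        with pytest.raises(ValueError, match="'z'"):
            run_nested(train, test, ["a", "z"], ORACLE, seed=0)

    def test_empty_test_pool_makes_remaining_levels_noops(self):
        train = _dataset(["a", "a", "b", "b"])
        test = _dataset(["a", "a"], seed=4)
        result = run_nested(train, test, ["a", "b"], ORACLE, seed=0, order="listed")
        assert result.n_outliers == 0
        assert result.levels[1].skipped
        assert result.levels[1].n_assigned == 0

    def test_explicit_order_override(self):
        train = _dataset(["a", "a", "b", "b"])
        test = _dataset(["a", "b"], seed=5)
        result = run_nested(train, test, ["a", "b"], ORACLE, seed=0, order=["b", "a"])
        assert result.activities == ("b", "a")

    def test_random_order_is_seeded(self):
        train = _dataset(["a", "a", "b", "b", "c", "c"])
        test = _dataset(["a", "b"], seed=5)
        acts = ["a", "b", "c"]
        r1 = run_nested(train, test, acts, ORACLE, seed=12)
        r2 = run_nested(train, test, acts, ORACLE, seed=12)
        assert r1.activities == r2.activities


def _assert_partition(result, test):
    assigned = sum(lv.n_assigned for lv in result.levels)
    assert assigned + result.n_outliers == len(test)
    # every test index appears exactly once across levels + outlier set
    seen = list(result.outlier_indices)
    for lv in result.levels:
        seen.extend(lv.assigned_indices)
    assert sorted(seen) == sorted(test.index)


@pytest.mark.parametrize("algorithm", ["knn", "cart", "svm", "nb", "lr"])
def test_partition_invariant_all_bases(algorithm):
    """Assigned + outliers = |test| for every base classifier and seed."""
    for seed in range(5):
        rng = np.random.default_rng(100 + seed)
        train = random_feature_dataset(
            rng, 80, ["a", "b", "c", "x"], min_per_class=10
        )
        test = random_feature_dataset(rng, 40, ["a", "b", "c", "x"])
        base = BaseClassifierConfig(algorithm=algorithm)
        result = run_nested(train, test, ["a", "b", "c"], base, seed=seed)
        _assert_partition(result, test)


def test_monotone_test_pool_shrinkage():
    rng = np.random.default_rng(7)
    train = random_feature_dataset(rng, 60, ["a", "b", "c"], min_per_class=10)
    test = random_feature_dataset(rng, 30, ["a", "b", "c", "x"])
    result = run_nested(train, test, ["a", "b", "c"],
                        BaseClassifierConfig("cart"), seed=1)
    pools = [lv.n_test_pool for lv in result.levels if not lv.skipped]
    assert all(a >= b for a, b in zip(pools, pools[1:]))


@pytest.mark.parametrize("seed", range(30))
def test_oracle_outliers_are_exactly_unknown_labels(seed):
    """With the oracle base, residual records = labels outside A, always."""
    rng = np.random.default_rng(seed)
    classes = ["a", "b", "c", "d", "out1", "out2"]
    known = ["a", "b", "c", "d"]
    train = random_feature_dataset(rng, 50, classes, min_per_class=2)
    test = random_feature_dataset(rng, int(rng.integers(5, 60)), classes)
    result = run_nested(train, test, known, ORACLE, seed=seed)
    expected = set(test.index[~test.labels.isin(known)])
    assert set(result.outlier_indices) == expected
    _assert_partition(result, test)


def test_model_results_shape(outlier_stream):
    """Model object -> fit() -> results with summary and report."""
    from nestout.features import build_feature_dataset
    from nestout.windowing import PRESETS

    ds = build_feature_dataset(outlier_stream, PRESETS["inertia"])
    model = NestedBinaryClassifier.from_dataframe(
        ds.to_frame(),
        activities=["sitting", "standing", "walking", "jogging"],
        seed=3,
    )
    result = model.fit()
    frame = result.level_frame()
    assert list(frame["level"]) == [1, 2, 3, 4]
    assert {"ACC", "PP", "SE", "SP"} <= set(frame.columns)
    text = result.summary()
    assert "residual outliers" in text and "Outlier accounting" in text
    report = result.outlier_report()
    assert report.n_detected + report.n_overdetected == result.n_outliers
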