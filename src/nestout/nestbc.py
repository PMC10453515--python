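"""Nested one-vs-rest elimination classification (NestBC).

Given an ordered set of k known activities, the cascade runs one level per
activity.  At level i the remaining training pool is relabelled 1 for the
current activity and 0 for everything else, a binary base classifier is
fitted, and the remaining test pool is predicted: records predicted 1
receive the current activity as their final label and leave the test pool,
while training records whose true label is the current activity leave the
training pool.  Records that survive all k levels were recognised by no
classifier and are reported as outlier activities.

Training labels outside the activity set are legal: such records are
permanent negatives — they are never the positive class and are never
removed — which is exactly what lets distance-based classifiers route
unknown-activity test records past every level.

The module follows the model/results convention: build a
:class:`NestedBinaryClassifier` from feature datasets, call ``fit()``, and
inspect the returned :class:`NestBCResults` (per-level models and metrics,
final assignments, the outlier set, and ``summary()``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .evaluation import (
    ConfusionMatrix,
    OutlierReport,
    binary_metrics,
    outlier_report,
    render_level_table,
)
from .features import FeatureDataset

__all__ = [
    "OUTLIER_LABEL",
    "BaseClassifierConfig",
    "split_train_test",
    "relabel_binary",
    "run_nested",
    "LevelResult",
    "NestBCResults",
    "NestedBinaryClassifier",
]

OUTLIER_LABEL = "OUTLIER"

#: Algorithms with their fixed hyperparameters: k-NN with 7 neighbours,
#: CART with unlimited depth, SVM with library defaults, Gaussian naive
#: Bayes, logistic regression capped at 500 iterations.  "oracle" is a
#: test-only base that recognises records from their true labels.
ALGORITHMS = ("knn", "cart", "svm", "nb", "lr", "oracle")
_SCALED = {"knn", "svm", "lr"}  # scale-sensitive bases get standardization


@dataclass(frozen=True)
class BaseClassifierConfig:
    """Which binary base classifier each level fits, and with what settings."""

    algorithm: str = "knn"
    n_neighbors: int = 7
    lr_max_iter: int = 500
    estimator_factory: Callable[[int], object] | None = None

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS and self.estimator_factory is None:
            raise ValueError(
                f"unknown base algorithm {self.algorithm!r}; expected one of {ALGORITHMS}"
            )

    def make(self, seed: int):
        """Instantiate a fresh (unfitted) binary estimator for one level."""
        if self.estimator_factory is not None:
            return self.estimator_factory(seed)
        if self.algorithm == "knn":
            est = KNeighborsClassifier(n_neighbors=self.n_neighbors)
        elif self.algorithm == "cart":
            est = DecisionTreeClassifier(max_depth=None, random_state=seed)
        elif self.algorithm == "svm":
            est = SVC(random_state=seed)
        elif self.algorithm == "nb":
            est = GaussianNB()
        elif self.algorithm == "lr":
            est = LogisticRegression(max_iter=self.lr_max_iter, random_state=seed)
        else:
            raise ValueError("the oracle base has no estimator; it is handled in-run")
        if self.algorithm in _SCALED:
            return Pipeline([("scale", StandardScaler()), ("clf", est)])
        return est


def split_train_test(
    dataset: FeatureDataset, train_fraction: float = 0.7, seed: int = 0
) -> tuple[FeatureDataset, FeatureDataset]:
    """Seeded random partition into train/test with |train| = round(f*n)."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    n = len(dataset)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    n_train = int(math.floor(train_fraction * n + 0.5))
    if n_train == 0 or n_train == n:
        raise ValueError("train_fraction leaves one side of the split empty")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    idx = dataset.index
    train_idx = idx[np.sort(perm[:n_train])]
    test_idx = idx[np.sort(perm[n_train:])]
    return dataset.take(train_idx), dataset.take(test_idx)


def relabel_binary(dataset: FeatureDataset, activity: str) -> FeatureDataset:
    """Copy of ``dataset`` with labels 1 (== activity) / 0 (everything else)."""
    binary = (dataset.labels == activity).astype(int)
    return FeatureDataset(dataset.features.copy(), binary)


@dataclass
class LevelResult:
    """One nesting level: the activity it recognised and how it did."""

    level: int
    activity: str
    model: object | None
    cm: ConfusionMatrix | None
    metrics: dict[str, float] | None
    n_test_pool: int
    n_assigned: int
    assigned_indices: pd.Index
    n_train_removed: int
    skipped: bool = False


@dataclass
class NestBCResults:
    """Outcome of a nested elimination run.

    ``assignment`` maps every test record to its final activity or to
    ``OUTLIER_LABEL``; ``outlier_indices`` is the residual test pool after
    the last level.  Every test record appears in exactly one level's
    assignments or in the outlier set.
    """

    levels: list[LevelResult]
    assignment: pd.Series
    outlier_indices: pd.Index
    activities: tuple[str, ...]
    seed: int
    algorithm: str
    _true_test_labels: pd.Series = field(repr=False, default=None)

    @property
    def n_outliers(self) -> int:
        return len(self.outlier_indices)

    def level_frame(self) -> pd.DataFrame:
        """Per-level metrics as a tidy table (fractions, not percent)."""
        rows = []
        for lv in self.levels:
            row = {
                "level": lv.level,
                "activity": lv.activity,
                "n_test_pool": lv.n_test_pool,
                "n_assigned": lv.n_assigned,
                "n_train_removed": lv.n_train_removed,
                "skipped": lv.skipped,
            }
            row.update(lv.metrics or {})
            rows.append(row)
        return pd.DataFrame(rows)

    def outlier_report(self, true_labels: pd.Series | None = None) -> OutlierReport:
        labels = self._true_test_labels if true_labels is None else true_labels
        if labels is None:
            raise ValueError("true test labels are required for an outlier report")
        return outlier_report(self, labels)

    def summary(self) -> str:
        lines = [
            "Nested binary classification (one-vs-rest elimination)",
            f"  base classifier : {self.algorithm}",
            f"  activity order  : {', '.join(self.activities)}",
            f"  test records    : {len(self.assignment)}",
            f"  residual outliers: {self.n_outliers}",
            "",
            "Per-level binary quality (percent):",
            render_level_table(self.levels),
        ]
        if self._true_test_labels is not None:
            rep = self.outlier_report()
            lines += [
                "",
                "Outlier accounting:",
                f"  true outliers   : {rep.n_true_outliers}",
                f"  detected        : {rep.n_detected}"
                f" ({rep.detection_pct:.2f}%)",
                f"  overdetected    : {rep.n_overdetected}",
            ]
        return "\n".join(lines)


def _activity_order(
    activities: Sequence[str], seed: int, order: Sequence[str] | str | None
) -> tuple[str, ...]:
    activities = tuple(activities)
    if len(set(activities)) != len(activities):
        raise ValueError("activity names must be unique")
    if order is None or order == "random":
        rng = np.random.default_rng(seed)
        return tuple(np.array(activities, dtype=object)[rng.permutation(len(activities))])
    if order == "listed":
        return activities
    order = tuple(order)
    if sorted(order) != sorted(activities):
        raise ValueError("explicit order must be a permutation of the activity set")
    return order


def run_nested(
    train: FeatureDataset,
    test: FeatureDataset,
    activities: Sequence[str],
    base: BaseClassifierConfig | None = None,
    seed: int = 0,
    order: Sequence[str] | str | None = None,
) -> NestBCResults:
    """Run the elimination cascade; see the module docstring for the loop.

    ``order`` may be None/"random" (seeded shuffle of the activity set,
    the default), "listed", or an explicit permutation.  Test labels
    outside the activity set are true outliers; they are used only for
    per-level metrics and the outlier report, never for prediction.
    """
    base = base or BaseClassifierConfig()
    acts = _activity_order(activities, seed, order)
    for a in acts:
        if not (train.labels == a).any():
            raise ValueError(f"activity {a!r} has no training records")

    train_pool = train.index
    test_pool = test.index
    assignment = pd.Series(OUTLIER_LABEL, index=test.index, dtype=object)
    levels: list[LevelResult] = []

    for i, activity in enumerate(acts, start=1):
        n_train_pos = int((train.labels.loc[train_pool] == activity).sum())
        if len(test_pool) == 0:
            # nothing left to classify: remaining levels are no-ops
            levels.append(
                LevelResult(
                    level=i, activity=activity, model=None, cm=None,
                    metrics=None, n_test_pool=0, n_assigned=0,
                    assigned_indices=pd.Index([]), n_train_removed=0,
                    skipped=True,
                )
            )
            continue
        if n_train_pos == 0:
            raise ValueError(
                f"level {i}: activity {activity!r} has no remaining training positives"
            )

        y_train = (train.labels.loc[train_pool] == activity).to_numpy(int)
        true_bin = (test.labels.loc[test_pool] == activity).to_numpy(int)
        if base.algorithm == "oracle" and base.estimator_factory is None:
            model = None
            pred = true_bin.copy()
        else:
            model = base.make(seed=seed + i)
            model.fit(train.features.loc[train_pool], y_train)
            pred = np.asarray(model.predict(test.features.loc[test_pool])).astype(int)

        cm = ConfusionMatrix.from_labels(true_bin, pred)
        assigned = test_pool[pred == 1]
        assignment.loc[assigned] = activity
        n_removed = int((train.labels.loc[train_pool] == activity).sum())
        levels.append(
            LevelResult(
                level=i, activity=activity, model=model, cm=cm,
                metrics=binary_metrics(cm), n_test_pool=len(test_pool),
                n_assigned=len(assigned), assigned_indices=assigned,
                n_train_removed=n_removed,
            )
        )
        test_pool = test_pool[pred == 0]
        train_pool = train_pool[(train.labels.loc[train_pool] != activity).to_numpy()]

    return NestBCResults(
        levels=levels,
        assignment=assignment,
        outlier_indices=test_pool,
        activities=acts,
        seed=seed,
        algorithm=base.algorithm,
        _true_test_labels=test.labels,
    )


class NestedBinaryClassifier:
    """Model object for nested elimination classification.

    Parameters
    ----------
    train, test
        Feature datasets.  Every activity in ``activities`` must occur in
        the training labels; test labels outside the set are true outliers.
    activities
        The known activity set A.  Defaults to the sorted training labels.
    base
        Base-classifier configuration (default: k-NN with 7 neighbours).
    order
        None/"random" for a seeded shuffle, "listed", or an explicit
        permutation of ``activities``.
    """

    def __init__(
        self,
        train: FeatureDataset,
        test: FeatureDataset,
        activities: Sequence[str] | None = None,
        base: BaseClassifierConfig | None = None,
        seed: int = 0,
        order: Sequence[str] | str | None = None,
    ) -> None:
        self.train = train
        self.test = test
        self.activities = (
            tuple(activities)
            if activities is not None
            else tuple(sorted(set(train.labels), key=str))
        )
        self.base = base or BaseClassifierConfig()
        self.seed = seed
        self.order = order

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        label_col: str = "label",
        activities: Sequence[str] | None = None,
        train_fraction: float = 0.7,
        base: BaseClassifierConfig | None = None,
        seed: int = 0,
        order: Sequence[str] | str | None = None,
    ) -> "NestedBinaryClassifier":
        """Build from one labelled feature table via a seeded 70/30 split."""
        dataset = FeatureDataset.from_frame(frame, label_col=label_col)
        train, test = split_train_test(dataset, train_fraction, seed)
        if activities is None:
            activities = tuple(sorted(set(train.labels), key=str))
        return cls(train, test, activities, base=base, seed=seed, order=order)

    def fit(self) -> NestBCResults:
        return run_nested(
            self.train, self.test, self.activities,
            base=self.base, seed=self.seed, order=self.order,
        )
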