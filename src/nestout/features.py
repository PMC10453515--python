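"""Per-window feature enrichment for inertial streams.

Each window keeps one base feature per sensor channel (the per-window mean)
and is enriched with ten statistics per acceleration axis: mean, median,
largest and smallest observation, standard deviation, energy, interquartile
range, entropy, correlation with the partner axis, and a simple moving
average.  With 3 base channels this yields 3 + 10*3 = 33 features per
window; with 12 base channels, 42.

Definitions used here (common HAR conventions; see docs/methods.md):

* standard deviation — population form (ddof 0);
* energy — mean of squared samples, ``(1/w) * sum(x_i^2)``;
* IQR — Q3 - Q1 with linear-interpolation quantiles;
* entropy — Shannon entropy in bits of the 10-bin histogram of the samples
  over their own range (0 for a constant window);
* correlation — Pearson r with the cyclic partner axis (x->y, y->z, z->x),
  0 when either axis is constant;
* SMA — mean of the trailing 5-sample moving-average series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import LabeledStream
from .windowing import Window, WindowSpec, segment

__all__ = [
    "STAT_NAMES",
    "N_ENTROPY_BINS",
    "window_stats",
    "enrich",
    "feature_names",
    "FeatureDataset",
    "build_feature_dataset",
]

STAT_NAMES = (
    "mean", "median", "max", "min", "std",
    "energy", "iqr", "entropy", "corr", "sma",
)
N_ENTROPY_BINS = 10
_SMA_SPAN = 5
AXIS_NAMES = ("accx", "accy", "accz")


def _histogram_entropy(x: np.ndarray) -> float:
    if np.ptp(x) == 0:
        return 0.0
    counts, _ = np.histogram(x, bins=N_ENTROPY_BINS)
    p = counts[counts > 0] / x.size
    return float(-(p * np.log2(p)).sum())


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def _sma(x: np.ndarray) -> float:
    rolling = pd.Series(x).rolling(_SMA_SPAN, min_periods=1).mean()
    return float(rolling.mean())


def window_stats(axis_samples, partner_axis_samples) -> dict[str, float]:
    """The ten per-axis statistics, keyed by :data:`STAT_NAMES`."""
    x = np.asarray(axis_samples, dtype=float)
    partner = np.asarray(partner_axis_samples, dtype=float)
    if x.size < 2 or partner.size < 2:
        raise ValueError("window statistics need at least 2 samples per axis")
    return {
        "mean": float(np.mean(x)),
        "median": float(np.median(x)),
        "max": float(np.max(x)),
        "min": float(np.min(x)),
        "std": float(np.std(x)),
        "energy": float(np.mean(x**2)),
        "iqr": float(np.percentile(x, 75) - np.percentile(x, 25)),
        "entropy": _histogram_entropy(x),
        "corr": _pearson(x, partner),
        "sma": _sma(x),
    }


def feature_names(base_channel_count: int, channel_names=None) -> list[str]:
    """Column names: per-channel base means, then the 30 axis statistics."""
    if channel_names is None:
        channel_names = [
            AXIS_NAMES[i] if i < 3 else f"ch{i}" for i in range(base_channel_count)
        ]
    names = [f"{ch}_base" for ch in channel_names]
    for axis in AXIS_NAMES:
        names.extend(f"{axis}_{stat}" for stat in STAT_NAMES)
    return names


def enrich(window, base_channel_count: int | None = None) -> np.ndarray:
    """Feature vector of one window: base means + 10 statistics x 3 axes.

    ``window`` is a :class:`~nestout.windowing.Window` or a (size, channels)
    array with the acceleration axes in the first three columns.  Output
    dimension is ``base_channel_count + 30``.
    """
    samples = window.samples if isinstance(window, Window) else np.asarray(window, float)
    samples = np.atleast_2d(samples)
    n_channels = samples.shape[1]
    if n_channels < 3:
        raise ValueError("enrichment needs >= 3 channels (acceleration axes first)")
    if base_channel_count is None:
        base_channel_count = n_channels
    if not 3 <= base_channel_count <= n_channels:
        raise ValueError("base_channel_count must cover the 3 axes and fit the window")

    base = samples[:, :base_channel_count].mean(axis=0)
    stats = []
    for axis in range(3):
        partner = (axis + 1) % 3  # cyclic x->y, y->z, z->x
        s = window_stats(samples[:, axis], samples[:, partner])
        stats.extend(s[name] for name in STAT_NAMES)
    return np.concatenate([base, np.array(stats)])


@dataclass
class FeatureDataset:
    """Per-window feature vectors plus activity labels.

    This is the container fed to classifiers: one row per window, constant
    column schema, and a label per row.  Row indices are preserved across
    subsetting so train/test pools can be tracked through elimination.
    """

    features: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels must have equal length")
        self.labels = self.labels.astype(object)
        if not self.features.index.equals(self.labels.index):
            self.labels.index = self.features.index

    def __len__(self) -> int:
        return len(self.features)

    @property
    def index(self) -> pd.Index:
        return self.features.index

    def take(self, index: pd.Index) -> "FeatureDataset":
        """Subset by row index labels, keeping the schema."""
        return FeatureDataset(self.features.loc[index], self.labels.loc[index])

    def copy(self) -> "FeatureDataset":
        return FeatureDataset(self.features.copy(), self.labels.copy())

    def to_frame(self) -> pd.DataFrame:
        out = self.features.copy()
        out["label"] = self.labels
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, label_col: str = "label") -> "FeatureDataset":
        return cls(frame.drop(columns=[label_col]), frame[label_col])


def build_feature_dataset(
    stream: LabeledStream,
    spec: WindowSpec,
    channel_names=None,
) -> FeatureDataset:
    """Segment ``stream`` and enrich every window into one feature row."""
    windows = segment(stream, spec)
    rows = [enrich(w) for w in windows]
    names = feature_names(stream.n_channels, channel_names)
    features = pd.DataFrame(rows, columns=names)
    labels = pd.Series([w.label for w in windows], dtype=object, name="label")
    return FeatureDataset(features, labels)
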