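"""Sliding-window segmentation of labelled streams.

Streams are compressed into fixed-size windows that overlap by a fraction
``p``: the step between window starts is ``max(1, round(w*(1-p)))`` samples,
and trailing samples that do not fill a whole window are discarded.  Each
window is assigned a single activity label by per-sample majority vote.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .synthetic import LabeledStream

__all__ = ["WindowSpec", "Window", "PRESETS", "window_starts", "label_window", "segment"]


@dataclass(frozen=True)
class WindowSpec:
    """Window size in samples and overlap fraction in [0, 1)."""

    size: int
    overlap: float = 0.5

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("window size must be >= 2 samples")
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must lie in [0, 1)")

    @property
    def step(self) -> int:
        # round-half-away-from-zero keeps a stated 80% overlap closest to
        # 80% when w*(1-p) is fractional (e.g. 144 * 0.2 = 28.8 -> 29)
        return max(1, int(math.floor(self.size * (1.0 - self.overlap) + 0.5)))


#: Window presets matching the three dataset families this pipeline targets.
PRESETS: dict[str, WindowSpec] = {
    "inertia": WindowSpec(40, 0.5),
    "wisdm": WindowSpec(144, 0.8),
    "uci": WindowSpec(128, 0.5),
}


@dataclass
class Window:
    """One fixed-length sample block with its majority activity label."""

    start: int
    samples: np.ndarray  # (size, n_channels)
    label: str


def window_starts(n_samples: int, spec: WindowSpec) -> range:
    """Start indices of all complete windows in a stream of ``n_samples``."""
    if n_samples < spec.size:
        raise ValueError(
            f"stream of {n_samples} samples is shorter than window size {spec.size}"
        )
    return range(0, n_samples - spec.size + 1, spec.step)


def label_window(window_labels) -> str:
    """Majority per-sample label; ties go to the earliest-occurring label."""
    labels = list(window_labels)
    if not labels:
        raise ValueError("cannot label an empty window")
    counts = Counter(labels)
    best = max(counts.values())
    for lab in labels:
        if counts[lab] == best:
            return lab
    raise AssertionError("unreachable")


def segment(stream: LabeledStream, spec: WindowSpec) -> list[Window]:
    """Cut ``stream`` into overlapping windows of ``spec.size`` samples."""
    out = []
    for start in window_starts(stream.n_samples, spec):
        stop = start + spec.size
        out.append(
            Window(
                start=start,
                samples=stream.channels[start:stop],
                label=label_window(stream.labels[start:stop]),
            )
        )
    return out
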