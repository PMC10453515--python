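"""Synthetic labelled tri-axial inertial streams.

Real deployments record accelerometer streams while a subject moves through
a sequence of activities (sitting, walking, jogging, ...).  This module
emulates such recordings: each activity is a per-axis signal model
(constant offset + sinusoid + Gaussian noise), a schedule strings activity
bouts together into one uniformly sampled stream, and short bouts of a
held-out activity can be spliced in afterwards to imitate outlier
activities occurring inside known ones.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ActivityProfile",
    "Schedule",
    "LabeledStream",
    "generate_stream",
    "inject_outliers",
    "write_wisdm_lines",
    "write_wisdm_csv",
    "default_profiles",
    "default_outlier_profile",
    "default_schedule",
]

#: Fixed per-axis phase offsets.  Distinct phases give the three axes a
#: non-trivial cross-correlation structure, which exercises the
#: cross-axis correlation feature downstream.
AXIS_PHASES = (0.0, np.pi / 3.0, 2.0 * np.pi / 3.0)


def _per_axis(value, name: str) -> tuple[float, float, float]:
    """Broadcast a scalar to three axes, or validate a 3-tuple."""
    if np.isscalar(value):
        value = (value, value, value)
    value = tuple(float(v) for v in value)
    if len(value) != 3:
        raise ValueError(f"{name} must be a scalar or a 3-tuple, got {value!r}")
    return value


@dataclass(frozen=True)
class ActivityProfile:
    """Per-axis generative model of one activity's acceleration signal.

    Each of the three axes follows

        baseline + amplitude * sin(2*pi*frequency*t + phase) + N(0, noise_sd)

    with the fixed phases in :data:`AXIS_PHASES`.  Units: baseline and
    amplitude in m/s^2, frequency in Hz, noise_sd in m/s^2.  Static
    activities use amplitude ~ 0; dynamic ones use a visible sinusoid.
    """

    name: str
    baseline: tuple[float, float, float] = (0.0, 9.81, 0.0)
    amplitude: tuple[float, float, float] = (0.0, 0.0, 0.0)
    frequency: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sd: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "baseline", _per_axis(self.baseline, "baseline"))
        object.__setattr__(self, "amplitude", _per_axis(self.amplitude, "amplitude"))
        object.__setattr__(self, "frequency", _per_axis(self.frequency, "frequency"))
        object.__setattr__(self, "noise_sd", _per_axis(self.noise_sd, "noise_sd"))
        if any(s < 0 for s in self.noise_sd):
            raise ValueError("noise_sd must be >= 0")
        if any(f < 0 for f in self.frequency):
            raise ValueError("frequency must be >= 0")

    def signal(self, t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Sample the 3-axis signal at times ``t`` (seconds)."""
        t = np.asarray(t, dtype=float)
        out = np.empty((t.size, 3))
        for axis in range(3):
            clean = self.baseline[axis] + self.amplitude[axis] * np.sin(
                2.0 * np.pi * self.frequency[axis] * t + AXIS_PHASES[axis]
            )
            if self.noise_sd[axis] > 0:
                clean = clean + rng.normal(0.0, self.noise_sd[axis], size=t.size)
            out[:, axis] = clean
        return out


@dataclass(frozen=True)
class Schedule:
    """Ordered activity bouts and the constant sampling interval (seconds)."""

    segments: tuple[tuple[str, float], ...]
    sampling_interval: float = 0.05

    def __post_init__(self) -> None:
        segments = tuple((str(name), float(dur)) for name, dur in self.segments)
        object.__setattr__(self, "segments", segments)
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be > 0")
        if any(dur <= 0 for _, dur in segments):
            raise ValueError("segment durations must be > 0")

    @property
    def total_duration(self) -> float:
        return sum(dur for _, dur in self.segments)


@dataclass
class LabeledStream:
    """Uniformly sampled multi-channel sensor stream with per-sample labels.

    ``channels`` is an (n_samples, n_channels) array with the three
    acceleration axes x/y/z first; ``labels`` holds one activity name per
    sample.
    """

    timestamps: np.ndarray
    channels: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.channels = np.atleast_2d(np.asarray(self.channels, dtype=float))
        self.labels = np.asarray(self.labels, dtype=object)
        n = self.timestamps.size
        if self.channels.shape[0] != n or self.labels.size != n:
            raise ValueError("timestamps, channels and labels must have equal length")
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.timestamps.size

    @property
    def n_channels(self) -> int:
        return self.channels.shape[1]

    @property
    def sampling_interval(self) -> float:
        if self.n_samples < 2:
            raise ValueError("need >= 2 samples to infer the sampling interval")
        return float(np.median(np.diff(self.timestamps)))

    def copy(self) -> "LabeledStream":
        return LabeledStream(
            self.timestamps.copy(), self.channels.copy(), self.labels.copy()
        )


class ConfigurationError(ValueError):
    """A schedule/profile combination that cannot be generated."""


def generate_stream(
    profiles, schedule: Schedule, seed: int
) -> LabeledStream:
    """Generate a labelled stream following ``schedule``.

    Each scheduled bout contributes round(duration / sampling_interval)
    samples from its activity's profile; the sinusoid phase is continuous
    across bouts because signals are evaluated at the global timestamp.
    The same (profiles, schedule, seed) triple always yields a bitwise
    identical stream.
    """
    by_name: dict[str, ActivityProfile] = {}
    for p in profiles:
        if p.name in by_name:
            raise ConfigurationError(f"duplicate activity profile {p.name!r}")
        by_name[p.name] = p
    for name, _ in schedule.segments:
        if name not in by_name:
            raise ConfigurationError(f"schedule activity {name!r} has no profile")

    rng = np.random.default_rng(seed)
    dt = schedule.sampling_interval
    blocks, labels = [], []
    start = 0
    for name, duration in schedule.segments:
        n = int(round(duration / dt))
        t = (start + np.arange(n)) * dt
        blocks.append(by_name[name].signal(t, rng))
        labels.extend([name] * n)
        start += n
    channels = np.vstack(blocks)
    timestamps = np.arange(start) * dt
    return LabeledStream(timestamps, channels, np.array(labels, dtype=object))


def inject_outliers(
    stream: LabeledStream,
    outlier_profile: ActivityProfile,
    n_segments: int,
    segment_duration: float,
    seed: int,
) -> LabeledStream:
    """Replace seeded-random spans of ``stream`` with an outlier activity.

    ``n_segments`` non-overlapping spans of ``segment_duration`` seconds are
    chosen uniformly at random; their samples are overwritten with the
    outlier profile's signal and relabelled with its name.  The stream
    length and timing are unchanged (replacement, not insertion).
    """
    if n_segments == 0:
        return stream.copy()
    dt = stream.sampling_interval
    total = stream.n_samples * dt
    if n_segments * segment_duration >= total:
        raise ValueError("outlier segments do not fit inside the stream")
    span = int(round(segment_duration / dt))
    if span < 1:
        raise ValueError("segment_duration shorter than one sample")

    rng = np.random.default_rng(seed)
    placed: list[int] = []
    attempts = 0
    while len(placed) < n_segments:
        attempts += 1
        if attempts > 10_000:
            raise RuntimeError(
                "could not place non-overlapping outlier segments; "
                "reduce n_segments or segment_duration"
            )
        cand = int(rng.integers(0, stream.n_samples - span + 1))
        if all(cand + span <= s or s + span <= cand for s in placed):
            placed.append(cand)

    out = stream.copy()
    for start in sorted(placed):
        t = out.timestamps[start : start + span]
        out.channels[start : start + span, :3] = outlier_profile.signal(t, rng)
        out.labels[start : start + span] = outlier_profile.name
    return out


# ---------------------------------------------------------------------------
# WISDM-schema export (user,activity,timestamp_ns,x,y,z with trailing ";")

def write_wisdm_lines(stream: LabeledStream, user: int = 33) -> list[str]:
    """Render the stream in the raw WISDM CSV dialect (one line per sample)."""
    lines = []
    for i in range(stream.n_samples):
        ts_ns = int(round(stream.timestamps[i] * 1e9))
        x, y, z = stream.channels[i, :3]
        lines.append(
            f"{user},{stream.labels[i]},{ts_ns},{x:.6f},{y:.6f},{z:.6f};"
        )
    return lines


def write_wisdm_csv(stream: LabeledStream, path: str | os.PathLike, user: int = 33) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(write_wisdm_lines(stream, user=user)) + "\n")


# ---------------------------------------------------------------------------
# Default study conditions: four known activities plus one held-out
# activity used as the injected outlier.  Baseline gaps are large relative
# to the noise so per-window means of different activities separate.

def default_profiles() -> list[ActivityProfile]:
    return [
        ActivityProfile(
            "sitting", baseline=(0.5, 9.8, 0.5), amplitude=0.0,
            frequency=0.0, noise_sd=0.05,
        ),
        ActivityProfile(
            "standing", baseline=(-0.5, 9.6, -0.5), amplitude=0.0,
            frequency=0.0, noise_sd=0.05,
        ),
        ActivityProfile(
            "walking", baseline=(0.0, 9.8, 0.0), amplitude=(1.5, 2.0, 1.0),
            frequency=2.0, noise_sd=0.3,
        ),
        ActivityProfile(
            "jogging", baseline=(0.0, 9.5, 0.0), amplitude=(3.0, 4.0, 2.5),
            frequency=2.8, noise_sd=0.5,
        ),
    ]


def default_outlier_profile() -> ActivityProfile:
    # stair climbing: intermediate amplitude, its own offsets and cadence
    return ActivityProfile(
        "stairs", baseline=(0.8, 9.2, -0.8), amplitude=(2.0, 2.5, 1.8),
        frequency=1.4, noise_sd=0.4,
    )


def default_schedule(
    cycle_seconds: float = 30.0,
    n_cycles: int = 10,
    sampling_interval: float = 0.05,
) -> Schedule:
    """Cycle the four default activities in 30 s bouts (20 Hz sampling)."""
    names = [p.name for p in default_profiles()]
    segments = tuple(
        (name, cycle_seconds) for _ in range(n_cycles) for name in names
    )
    return Schedule(segments=segments, sampling_interval=sampling_interval)
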