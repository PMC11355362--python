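"""Core in-memory containers for ECG and inter-beat-interval (IBI) data.

The substrate of every HRV computation in this package is the IBI series:
the sequence of times between consecutive R-wave peaks of the ECG, in
milliseconds. An :class:`IBISeries` carries the beat timestamps, the
interval durations derived from them, per-interval artifact flags, and a
log of any corrections applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ECGRecord", "IBISeries", "SampledSeries"]


@dataclass
class ECGRecord:
    """A single-channel ECG trace.

    Parameters
    ----------
    fs_hz : float
        Sampling rate in Hz (must be positive).
    samples : ndarray
        Amplitude samples in mV.
    start_time_s : float
        Time of the first sample, in seconds.
    """

    fs_hz: float
    samples: np.ndarray
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValueError(f"fs_hz must be positive, got {self.fs_hz}")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs_hz

    @property
    def times_s(self) -> np.ndarray:
        return self.start_time_s + np.arange(len(self.samples)) / self.fs_hz


@dataclass
class IBISeries:
    """Timestamped inter-beat intervals with artifact annotations.

    ``beat_times_ms`` has one more element than ``intervals_ms``: interval
    ``k`` spans ``beat_times_ms[k]`` to ``beat_times_ms[k + 1]``. Intervals
    from the ECG path are rounded to the nearest millisecond; synthetic
    series may carry sub-millisecond precision.
    """

    beat_times_ms: np.ndarray
    intervals_ms: np.ndarray
    artifact_flags: np.ndarray = None  # type: ignore[assignment]
    correction_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beat_times_ms = np.asarray(self.beat_times_ms, dtype=float)
        self.intervals_ms = np.asarray(self.intervals_ms, dtype=float)
        if self.artifact_flags is None:
            self.artifact_flags = np.zeros(len(self.intervals_ms), dtype=bool)
        else:
            self.artifact_flags = np.asarray(self.artifact_flags, dtype=bool)
        if len(self.beat_times_ms) != len(self.intervals_ms) + 1:
            raise ValueError(
                "beat_times_ms must have exactly one more element than intervals_ms "
                f"(got {len(self.beat_times_ms)} times, {len(self.intervals_ms)} intervals)"
            )
        if len(self.artifact_flags) != len(self.intervals_ms):
            raise ValueError("artifact_flags and intervals_ms must have the same length")
        if np.any(np.diff(self.beat_times_ms) <= 0):
            raise ValueError("beat_times_ms must be strictly increasing")
        if np.any(self.intervals_ms <= 0):
            raise ValueError("all intervals must be positive")

    @classmethod
    def from_intervals(cls, intervals_ms, t0_ms: float = 0.0, **kw) -> "IBISeries":
        """Build a series from interval durations, beats at their cumulative sums."""
        intervals_ms = np.asarray(intervals_ms, dtype=float)
        beat_times = t0_ms + np.concatenate([[0.0], np.cumsum(intervals_ms)])
        return cls(beat_times, intervals_ms, **kw)

    @property
    def n_intervals(self) -> int:
        return len(self.intervals_ms)

    @property
    def total_time_ms(self) -> float:
        return float(self.beat_times_ms[-1] - self.beat_times_ms[0])

    @property
    def duration_s(self) -> float:
        return self.total_time_ms / 1000.0

    def is_integral(self) -> bool:
        """True when every interval is a whole number of milliseconds."""
        return bool(np.all(self.intervals_ms == np.rint(self.intervals_ms)))

    def copy(self) -> "IBISeries":
        return IBISeries(
            self.beat_times_ms.copy(),
            self.intervals_ms.copy(),
            self.artifact_flags.copy(),
            list(self.correction_log),
        )


@dataclass
class SampledSeries:
    """A uniformly sampled signal (used for the interpolated heart-period series)."""

    fs_hz: float
    values: np.ndarray
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self.values)) / self.fs_hz

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.fs_hz
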