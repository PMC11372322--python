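"""Core containers for the pulse-interval pipeline.

The pipeline moves a recording through four representations: a
time-stamped frame-luminosity series (:class:`FrameSeries`, the raw
camera PPG), a uniformly sampled signal (:class:`UniformSignal`, used
for the filtered/resampled PPG and for the ECG), a set of detected
local maxima (:class:`PeakSet`), and a per-beat interval sequence with
rejection codes (:class:`IntervalSeries`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InvalidInputError",
    "AlignmentError",
    "FrameSeries",
    "UniformSignal",
    "PeakSet",
    "IntervalSeries",
    "VALID",
    "REJECTED_QUARTILE",
    "REJECTED_SUCCESSIVE",
    "REJECTED_RATE_BOUNDS",
    "STATUS_CODES",
]


class InvalidInputError(ValueError):
    """Raised when an input violates an operation's preconditions."""


class AlignmentError(RuntimeError):
    """Raised when two recordings cannot be time-aligned or paired."""


# Per-interval status codes used by IntervalSeries.
VALID = "valid"
REJECTED_QUARTILE = "rejected_quartile"
REJECTED_SUCCESSIVE = "rejected_successive"
REJECTED_RATE_BOUNDS = "rejected_rate_bounds"
STATUS_CODES = (VALID, REJECTED_QUARTILE, REJECTED_SUCCESSIVE, REJECTED_RATE_BOUNDS)


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise InvalidInputError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class FrameSeries:
    """Time-stamped per-frame mean luminosity (raw camera PPG).

    Parameters
    ----------
    times : array-like
        Frame timestamps in seconds, strictly increasing.
    values : array-like
        Mean frame luminosity (arbitrary units).
    nominal_rate : float
        Nominal frame rate in frames/s (default 30).
    """

    times: np.ndarray
    values: np.ndarray
    nominal_rate: float = 30.0

    def __post_init__(self):
        times = _as_float_array(self.times, "times")
        values = _as_float_array(self.values, "values")
        if len(times) != len(values):
            raise InvalidInputError("times and values must have equal length")
        if len(times) < 2:
            raise InvalidInputError("FrameSeries needs at least 2 frames")
        if np.any(np.diff(times) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if self.nominal_rate <= 0:
            raise InvalidInputError("nominal_rate must be positive")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class UniformSignal:
    """Uniformly sampled 1-D signal with a sampling rate in Hz."""

    start_time: float
    rate: float
    values: np.ndarray

    def __post_init__(self):
        if self.rate <= 0:
            raise InvalidInputError("rate must be positive")
        values = _as_float_array(self.values, "values")
        object.__setattr__(self, "values", values)

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.values)) / self.rate

    @property
    def duration(self) -> float:
        return (len(self.values) - 1) / self.rate

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class PeakSet:
    """Detected local maxima: times, sample indices and prominences."""

    peak_times: np.ndarray
    peak_indices: np.ndarray
    prominences: np.ndarray

    def __post_init__(self):
        times = _as_float_array(self.peak_times, "peak_times")
        proms = _as_float_array(self.prominences, "prominences")
        idx = np.asarray(self.peak_indices, dtype=np.intp)
        if not (len(times) == len(idx) == len(proms)):
            raise InvalidInputError("PeakSet fields must have equal length")
        if len(times) > 1 and np.any(np.diff(times) <= 0):
            raise InvalidInputError("peak_times must be strictly increasing")
        if np.any(proms < 0):
            raise InvalidInputError("prominences must be non-negative")
        object.__setattr__(self, "peak_times", times)
        object.__setattr__(self, "peak_indices", idx)
        object.__setattr__(self, "prominences", proms)

    def __len__(self) -> int:
        return len(self.peak_times)

    def take(self, mask_or_indices) -> "PeakSet":
        """Subset of the peaks, order preserved."""
        return PeakSet(
            self.peak_times[mask_or_indices],
            self.peak_indices[mask_or_indices],
            self.prominences[mask_or_indices],
        )


@dataclass(frozen=True)
class IntervalSeries:
    """Per-beat interval sequence in ms with per-interval status codes.

    ``beat_times[i]`` is the time (s) of the peak *ending* interval
    ``i``; ``status[i]`` is one of :data:`STATUS_CODES`. Filters mark
    statuses but never change interval values.
    """

    beat_times: np.ndarray
    intervals: np.ndarray
    status: np.ndarray = field(default=None)

    def __post_init__(self):
        bt = _as_float_array(self.beat_times, "beat_times")
        iv = _as_float_array(self.intervals, "intervals")
        if len(bt) != len(iv):
            raise InvalidInputError("beat_times and intervals must have equal length")
        if len(bt) == 0:
            raise InvalidInputError("IntervalSeries may not be empty")
        if np.any(iv <= 0):
            raise InvalidInputError("intervals must be positive")
        if np.any(np.diff(bt) <= 0):
            raise InvalidInputError("beat_times must be strictly increasing")
        status = self.status
        if status is None:
            status = np.full(len(iv), VALID, dtype=object)
        else:
            status = np.asarray(status, dtype=object)
            if len(status) != len(iv):
                raise InvalidInputError("status length mismatch")
            bad = set(status) - set(STATUS_CODES)
            if bad:
                raise InvalidInputError(f"unknown status codes: {bad}")
        object.__setattr__(self, "beat_times", bt)
        object.__setattr__(self, "intervals", iv)
        object.__setattr__(self, "status", status)

    @property
    def valid_mask(self) -> np.ndarray:
        return self.status == VALID

    @property
    def valid_intervals(self) -> np.ndarray:
        return self.intervals[self.valid_mask]

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def with_status(self, status: np.ndarray) -> "IntervalSeries":
        """Copy with a replacement status array (values untouched)."""
        return IntervalSeries(self.beat_times, self.intervals, status)

    def __len__(self) -> int:
        return len(self.intervals)
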