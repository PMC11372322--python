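"""Pulse-interval computation and multistep artifact rejection.

Intervals are the times between successive valid peaks, in ms. The
artifact screen has three stages, applied in order: a per-window
quartile fence over blocks of 200 intervals, a 20% successive-
difference rule, and physiological rate bounds (20-200 bpm). Stages
mark rejection codes and never alter interval values, so the valid set
only shrinks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .types import (
    REJECTED_QUARTILE,
    REJECTED_RATE_BOUNDS,
    REJECTED_SUCCESSIVE,
    IntervalSeries,
    InvalidInputError,
    PeakSet,
)

__all__ = [
    "CleaningConfig",
    "compute_intervals",
    "quartile_window_filter",
    "successive_difference_filter",
    "rate_bounds_filter",
    "clean_intervals",
    "rejection_summary",
]

log = logging.getLogger(__name__)


@dataclass
class CleaningConfig:
    """Artifact-rejection parameters.

    ``fence_multiplier`` widens the quartile window to Tukey fences
    ``[Q1 - m*IQR, Q3 + m*IQR]``; 0 recovers the literal reading in
    which everything outside ``[Q1, Q3]`` is removed (that reading
    discards about half of all beats, so the robust fence is the
    default).
    """

    window_intervals: int = 200
    fence_multiplier: float = 1.5
    successive_diff_fraction: float = 0.20
    min_bpm: float = 20.0
    max_bpm: float = 200.0

    def __post_init__(self):
        if self.window_intervals < 4:
            raise InvalidInputError("window_intervals must be >= 4")
        if self.fence_multiplier < 0:
            raise InvalidInputError("fence_multiplier must be >= 0")
        if not (0 < self.successive_diff_fraction < 1):
            raise InvalidInputError("successive_diff_fraction must lie in (0, 1)")
        if not (0 < self.min_bpm < self.max_bpm):
            raise InvalidInputError("need 0 < min_bpm < max_bpm")


def compute_intervals(peaks: PeakSet) -> IntervalSeries:
    """Successive peak-to-peak durations in ms; beat time is the ending peak."""
    if len(peaks) < 2:
        raise InvalidInputError("need at least 2 peaks to form an interval")
    intervals = np.diff(peaks.peak_times) * 1000.0
    return IntervalSeries(peaks.peak_times[1:], intervals)


def quartile_window_filter(series: IntervalSeries,
                           cfg: CleaningConfig | None = None) -> IntervalSeries:
    """Per-window quartile fences over consecutive blocks of valid intervals.

    Valid intervals are partitioned in time order into blocks of
    ``window_intervals`` (the last block may be shorter); within each
    block, intervals outside ``[Q1 - m*IQR, Q3 + m*IQR]`` are marked
    ``rejected_quartile``. Quartiles use linear interpolation between
    order statistics.
    """
    cfg = cfg or CleaningConfig()
    status = series.status.copy()
    valid_idx = np.nonzero(series.valid_mask)[0]
    for start in range(0, len(valid_idx), cfg.window_intervals):
        block = valid_idx[start:start + cfg.window_intervals]
        vals = series.intervals[block]
        q1, q3 = np.percentile(vals, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - cfg.fence_multiplier * iqr, q3 + cfg.fence_multiplier * iqr
        status[block[(vals < lo) | (vals > hi)]] = REJECTED_QUARTILE
    return series.with_status(status)


def successive_difference_filter(series: IntervalSeries,
                                 cfg: CleaningConfig | None = None) -> IntervalSeries:
    """Reject intervals that jump more than 20% from the last accepted one.

    Scanning valid intervals in time order, the first one is accepted
    and seeds the reference; each subsequent interval is rejected iff
    its relative difference from the *most recent accepted* interval
    exceeds the threshold. Rejected intervals never become the
    reference, so one artifact cannot poison later comparisons.
    """
    cfg = cfg or CleaningConfig()
    status = series.status.copy()
    ref = None
    for i in np.nonzero(series.valid_mask)[0]:
        x = series.intervals[i]
        if ref is None:
            ref = x
        elif abs(x - ref) / ref > cfg.successive_diff_fraction:
            status[i] = REJECTED_SUCCESSIVE
        else:
            ref = x
    return series.with_status(status)


def rate_bounds_filter(series: IntervalSeries,
                       cfg: CleaningConfig | None = None) -> IntervalSeries:
    """Reject intervals implying a heart rate below 20 or above 200 bpm.

    Bounds are exclusive: an interval of exactly 300 ms (200 bpm) or
    3000 ms (20 bpm) is kept.
    """
    cfg = cfg or CleaningConfig()
    status = series.status.copy()
    bpm = 60000.0 / series.intervals
    out = series.valid_mask & ((bpm < cfg.min_bpm) | (bpm > cfg.max_bpm))
    status[out] = REJECTED_RATE_BOUNDS
    return series.with_status(status)


def clean_intervals(series: IntervalSeries,
                    cfg: CleaningConfig | None = None) -> IntervalSeries:
    """The full multistep artifact screen, stages in narrative order."""
    cfg = cfg or CleaningConfig()
    counts = {}
    before = series.n_valid
    for stage in (quartile_window_filter, successive_difference_filter, rate_bounds_filter):
        series = stage(series, cfg)
        counts[stage.__name__] = before - series.n_valid
        before = series.n_valid
    log.info("interval cleaning rejections: %s (%d of %d valid remain)",
             counts, series.n_valid, len(series))
    return series


def rejection_summary(series: IntervalSeries) -> dict:
    """Counts of intervals per status code, plus the total."""
    out = {code: int(np.sum(series.status == code))
           for code in ("valid", REJECTED_QUARTILE, REJECTED_SUCCESSIVE,
                        REJECTED_RATE_BOUNDS)}
    out["total"] = len(series)
    return out
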