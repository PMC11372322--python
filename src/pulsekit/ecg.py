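"""Reference-ECG processing: R-wave detection and R-R intervals.

The detector targets clean resting lab ECG: a zero-phase high-pass
removes baseline wander, a short moving average tames wideband noise,
candidate maxima are thresholded on topographic prominence relative to
the strongest plausible beats, and a refractory rule keeps the taller
of two detections closer together than a minimum beat spacing. All
thresholds are relative, so detection is invariant to gain and offset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .intervals import compute_intervals
from .ppg import detect_local_maxima
from .types import IntervalSeries, InvalidInputError, PeakSet, UniformSignal

__all__ = ["EcgConfig", "detect_r_peaks", "compute_rr_intervals", "screen_ectopy"]

log = logging.getLogger(__name__)


@dataclass
class EcgConfig:
    """R-wave detector parameters.

    ``prominence_fraction`` scales the reference prominence — the
    median prominence of the strongest maxima, counting as many as a
    30 bpm rhythm could produce — into the acceptance threshold.
    ``refractory_ms`` is the minimum spacing between R-waves
    (250 ms = 240 bpm, above any plausible resting rate).
    """

    expected_rate: float = 500.0    # Hz
    highpass_hz: float = 5.0
    refractory_ms: float = 250.0
    prominence_fraction: float = 0.5
    smooth_ms: float = 12.0         # moving-average width before peak picking
    edge_guard_s: float = 0.9       # discard peaks this close to either record end

    def __post_init__(self):
        if self.expected_rate <= 100:
            raise InvalidInputError("expected_rate must exceed 100 Hz")
        if self.refractory_ms <= 0:
            raise InvalidInputError("refractory_ms must be positive")
        if not (0 < self.prominence_fraction < 1):
            raise InvalidInputError("prominence_fraction must lie in (0, 1)")


def _preprocess(ecg: UniformSignal, cfg: EcgConfig) -> np.ndarray:
    sos = sp_signal.butter(2, cfg.highpass_hz, btype="highpass",
                           fs=ecg.rate, output="sos")
    hp = sp_signal.sosfiltfilt(sos, ecg.values)
    width = max(1, int(round(cfg.smooth_ms / 1000.0 * ecg.rate)))
    if width > 1:
        kernel = np.ones(width) / width
        hp = np.convolve(np.pad(hp, width // 2, mode="reflect"),
                         kernel, mode="valid")[: len(ecg)]
    return hp


def detect_r_peaks(ecg: UniformSignal, cfg: EcgConfig | None = None) -> PeakSet:
    """Detect R-wave apex times in a uniformly sampled ECG.

    Returns one peak per accepted R-wave with its time, sample index
    and prominence on the preprocessed signal. A flat or empty-looking
    signal yields an empty :class:`PeakSet`.
    """
    cfg = cfg or EcgConfig()
    if ecg.rate < 100:
        raise InvalidInputError("ECG sampling rate must be >= 100 Hz")
    if ecg.duration < 10:
        raise InvalidInputError("ECG recording shorter than 10 s")
    empty = PeakSet(np.empty(0), np.empty(0, dtype=np.intp), np.empty(0))
    if np.ptp(ecg.values) <= 1e-12 * max(1.0, float(np.max(np.abs(ecg.values)))):
        return empty

    filtered = _preprocess(ecg, cfg)
    cand = detect_local_maxima(UniformSignal(ecg.start_time, ecg.rate, filtered))
    if len(cand) == 0:
        return empty

    # Reference prominence: median over the strongest maxima, taking as
    # many candidates as a 30 bpm rhythm would produce. A median over
    # *all* maxima would be dominated by noise wiggles.
    n_ref = max(3, int(ecg.duration / 2.0))
    top = np.sort(cand.prominences)[::-1][:n_ref]
    threshold = cfg.prominence_fraction * np.median(top)
    strong = cand.take(cand.prominences > threshold)
    if len(strong) == 0:
        return empty

    # Refractory rule: among detections closer than refractory_ms, keep
    # the taller (by filtered amplitude), scanning left to right.
    refractory_s = cfg.refractory_ms / 1000.0
    heights = filtered[strong.peak_indices]
    kept: list[int] = []
    for i in range(len(strong)):
        if kept and strong.peak_times[i] - strong.peak_times[kept[-1]] < refractory_s:
            if heights[i] > heights[kept[-1]]:
                kept[-1] = i
        else:
            kept.append(i)
    result = strong.take(np.asarray(kept, dtype=np.intp))
    # boundary guard: filter transients make edge detections unreliable
    t0, t1 = ecg.start_time, ecg.times[-1]
    result = result.take((result.peak_times >= t0 + cfg.edge_guard_s)
                         & (result.peak_times <= t1 - cfg.edge_guard_s))
    log.info("ecg r-peaks: %d maxima -> %d above threshold -> %d after refractory "
             "and edge guard", len(cand), len(strong), len(result))
    return result


def compute_rr_intervals(peaks: PeakSet) -> IntervalSeries:
    """R-R intervals in ms; same contract as PPG interval computation."""
    return compute_intervals(peaks)


def screen_ectopy(series: IntervalSeries, tolerance_fraction: float = 0.3):
    """Flag (never remove) intervals that deviate from a running median.

    Each interval is compared with the median of the 11 nearest
    intervals (centred window, truncated at the record ends); those
    deviating by more than ``tolerance_fraction`` of the median are
    flagged for human review, emulating the manual ectopy screen a
    technician would perform on lab ECG.

    Returns
    -------
    (series, report) : tuple
        The unmodified series and a dict with ``flagged_beat_times``,
        ``flagged_indices`` and ``n_flagged``.
    """
    n = len(series)
    if n < 11:
        raise InvalidInputError("ectopy screening needs at least 11 intervals")
    flagged = []
    for i in range(n):
        lo = max(0, min(i - 5, n - 11))
        med = np.median(series.intervals[lo:lo + 11])
        if abs(series.intervals[i] - med) / med > tolerance_fraction:
            flagged.append(i)
    report = {
        "flagged_indices": flagged,
        "flagged_beat_times": [float(series.beat_times[i]) for i in flagged],
        "n_flagged": len(flagged),
    }
    return series, report
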