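"""Raw-PPG processing: from frame luminosity to valid systolic-peak times.

The chain mirrors how camera-based pulse apps process a fingertip
recording: average each video frame to one luminosity value, band-pass
to the cardiac band (0.75-3 Hz), smooth with a short unit-sum window,
upsample with a cubic spline to 180 Hz for sub-frame peak timing, find
local maxima by neighbour comparison, then discard weak maxima twice —
once against 30% of the global mean prominence, once against 75% of the
mean prominence in a sliding 5-peak window (this second pass removes
dicrotic/diastolic bumps misread as beats).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import interpolate, signal

from .types import FrameSeries, InvalidInputError, PeakSet, UniformSignal

__all__ = [
    "PpgConfig",
    "average_frame_luminosity",
    "regularize_frames",
    "bandpass_filter",
    "smooth",
    "resample_cubic_spline",
    "detect_local_maxima",
    "prominence_filter_global",
    "prominence_filter_window",
    "extract_ppg_peaks",
]

log = logging.getLogger(__name__)


@dataclass
class PpgConfig:
    """Tunable parameters of the PPG peak-extraction chain.

    Defaults reproduce the pipeline constants: 0.75-3 Hz pass band,
    5-frame smoothing window, 180 Hz resampling, 30% global and 75%
    windowed prominence criteria over 5-peak windows.
    """

    band_low: float = 0.75          # Hz
    band_high: float = 3.0          # Hz
    filter_order: int = 2           # applied forward-backward (zero phase)
    smooth_window_len: int = 5      # frames
    smooth_window_shape: str = "hann"   # or "flat" (moving average)
    resample_rate: float = 180.0    # Hz
    global_prominence_fraction: float = 0.30
    window_prominence_fraction: float = 0.75
    prominence_window_peaks: int = 5
    invert: bool = True             # luminosity dips at systole; flip so beats are maxima
    max_jitter_fraction: float = 0.20   # tolerated timestamp deviation, fraction of frame period
    edge_guard_s: float = 0.8       # discard peaks this close to either record end

    def __post_init__(self):
        if not (0 < self.band_low < self.band_high):
            raise InvalidInputError("need 0 < band_low < band_high")
        if self.band_high >= self.resample_rate / 2:
            raise InvalidInputError("band_high must be below the resample Nyquist rate")
        for frac in (self.global_prominence_fraction, self.window_prominence_fraction):
            if not (0 < frac < 1):
                raise InvalidInputError("prominence fractions must lie in (0, 1)")
        if self.smooth_window_len < 3 or self.smooth_window_len % 2 == 0:
            raise InvalidInputError("smooth_window_len must be odd and >= 3")
        if self.prominence_window_peaks < 3 or self.prominence_window_peaks % 2 == 0:
            raise InvalidInputError("prominence_window_peaks must be odd and >= 3")
        if self.filter_order < 1:
            raise InvalidInputError("filter_order must be >= 1")


def average_frame_luminosity(frames, timestamps) -> FrameSeries:
    """Collapse each pixel-intensity frame to its mean luminosity.

    Parameters
    ----------
    frames : sequence of 2-D arrays
        Pixel intensities, one array per video frame.
    timestamps : array-like
        Frame times in seconds, strictly increasing.
    """
    timestamps = np.asarray(timestamps, dtype=float)
    if len(frames) != len(timestamps):
        raise InvalidInputError("frames and timestamps must have equal length")
    means = np.empty(len(frames))
    for i, frame in enumerate(frames):
        arr = np.asarray(frame, dtype=float)
        if arr.size == 0:
            raise InvalidInputError(f"frame {i} is empty")
        means[i] = arr.mean()
    return FrameSeries(timestamps, means)


def regularize_frames(raw: FrameSeries, cfg: PpgConfig | None = None) -> UniformSignal:
    """Treat a (possibly jittered) frame series as uniform at its nominal rate.

    Camera timestamps jitter slightly around the nominal frame grid; the
    filters downstream require uniform sampling. If any timestamp
    deviates from the nominal grid by more than ``max_jitter_fraction``
    of a frame period the series is refused rather than silently
    resampled.
    """
    cfg = cfg or PpgConfig()
    period = 1.0 / raw.nominal_rate
    grid = raw.times[0] + np.arange(len(raw)) * period
    jitter = np.max(np.abs(raw.times - grid))
    if jitter >= cfg.max_jitter_fraction * period:
        raise InvalidInputError(
            f"frame timestamps deviate up to {jitter * 1e3:.1f} ms from the nominal "
            f"{raw.nominal_rate:g} fps grid (tolerance "
            f"{cfg.max_jitter_fraction * period * 1e3:.1f} ms); resample upstream"
        )
    return UniformSignal(float(raw.times[0]), raw.nominal_rate, raw.values)


def bandpass_filter(sig: UniformSignal, cfg: PpgConfig | None = None) -> UniformSignal:
    """Zero-phase Butterworth band-pass to the cardiac band.

    The filter is applied forward and backward (``sosfiltfilt``) so peak
    times are not shifted; the effective attenuation is that of twice
    the design order.
    """
    cfg = cfg or PpgConfig()
    if sig.rate <= 2 * cfg.band_high:
        raise InvalidInputError("sampling rate must exceed twice band_high")
    sos = signal.butter(cfg.filter_order, [cfg.band_low, cfg.band_high],
                        btype="bandpass", fs=sig.rate, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)
    if len(sig) <= padlen:
        raise InvalidInputError(
            f"signal too short for zero-phase filtering (need > {padlen} samples)")
    return UniformSignal(sig.start_time, sig.rate, signal.sosfiltfilt(sos, sig.values))


def _smooth_window(length: int, shape: str) -> np.ndarray:
    if shape == "hann":
        w = np.hanning(length)
    elif shape == "flat":
        w = np.ones(length)
    else:
        raise InvalidInputError(f"unknown smooth_window_shape {shape!r}")
    return w / w.sum()


def smooth(sig: UniformSignal, cfg: PpgConfig | None = None) -> UniformSignal:
    """Convolve with a unit-sum window; reflection padding keeps the length."""
    cfg = cfg or PpgConfig()
    w = _smooth_window(cfg.smooth_window_len, cfg.smooth_window_shape)
    half = len(w) // 2
    if len(sig) < len(w):
        raise InvalidInputError("smoothing window longer than signal")
    padded = np.pad(sig.values, half, mode="reflect")
    out = np.convolve(padded, w, mode="valid")
    return UniformSignal(sig.start_time, sig.rate, out)


def resample_cubic_spline(sig: UniformSignal, cfg: PpgConfig | None = None) -> UniformSignal:
    """Resample onto a uniform grid (default 180 Hz) via a not-a-knot cubic spline."""
    cfg = cfg or PpgConfig()
    if len(sig) < 4:
        raise InvalidInputError("cubic spline resampling needs at least 4 samples")
    spline = interpolate.CubicSpline(sig.times, sig.values, bc_type="not-a-knot")
    n_out = math.floor(sig.duration * cfg.resample_rate) + 1
    new_times = sig.start_time + np.arange(n_out) / cfg.resample_rate
    return UniformSignal(sig.start_time, cfg.resample_rate, spline(new_times))


def detect_local_maxima(sig: UniformSignal) -> PeakSet:
    """Neighbour-comparison local maxima with topographic prominences.

    An index ``i`` is a peak iff ``values[i-1] < values[i]`` and
    ``values[i] >= values[i+1]``: a flat plateau yields its first
    sample. Prominence is the height of the peak above the higher of
    the two lowest descents toward a higher peak or the signal edge.
    """
    v = sig.values
    if len(v) < 3:
        raise InvalidInputError("need at least 3 samples to detect local maxima")
    rising = v[1:-1] > v[:-2]
    not_falling_into = v[1:-1] >= v[2:]
    idx = np.nonzero(rising & not_falling_into)[0] + 1
    if len(idx) == 0:
        return PeakSet(np.empty(0), np.empty(0, dtype=np.intp), np.empty(0))
    proms = signal.peak_prominences(v, idx)[0]
    times = sig.start_time + idx / sig.rate
    return PeakSet(times, idx, proms)


def prominence_filter_global(peaks: PeakSet, cfg: PpgConfig | None = None) -> PeakSet:
    """Keep peaks whose prominence exceeds a fraction of the mean prominence."""
    cfg = cfg or PpgConfig()
    if len(peaks) == 0:
        return peaks
    threshold = cfg.global_prominence_fraction * peaks.prominences.mean()
    return peaks.take(peaks.prominences > threshold)


def prominence_filter_window(peaks: PeakSet, cfg: PpgConfig | None = None) -> PeakSet:
    """Discard peaks weak relative to the mean prominence of a sliding window.

    For each peak, a window of ``prominence_window_peaks`` peaks centred
    on it is formed over the *input* peak list; near the ends the
    window is clamped so it keeps its full length while the list
    allows (shorter lists use all peaks). The peak is discarded iff its
    prominence is below ``window_prominence_fraction`` times the window
    mean. A single pass: removals do not re-enter the window means.
    """
    cfg = cfg or PpgConfig()
    n = len(peaks)
    if n == 0:
        return peaks
    win = cfg.prominence_window_peaks
    half = win // 2
    keep = np.empty(n, dtype=bool)
    for i in range(n):
        lo = min(max(0, i - half), max(0, n - win))
        hi = min(n, lo + win)
        keep[i] = peaks.prominences[i] >= (
            cfg.window_prominence_fraction * peaks.prominences[lo:hi].mean())
    return peaks.take(keep)


def extract_ppg_peaks(raw: FrameSeries, cfg: PpgConfig | None = None) -> PeakSet:
    """Full chain from raw frame luminosity to valid systolic-peak times.

    Applies, in order: timestamp regularization, optional sign flip
    (camera luminosity dips at systole), band-pass, smoothing, 180 Hz
    cubic-spline resampling, neighbour-comparison peak detection, the
    global 30% prominence filter and the windowed 75% prominence filter.
    Peaks within ``edge_guard_s`` of either record end are discarded:
    the zero-phase filter has boundary transients there and a peak's
    prominence lacks full support, so boundary detections are
    unreliable.
    """
    cfg = cfg or PpgConfig()
    if raw.duration < 10.0:
        raise InvalidInputError("recording shorter than 10 s")
    sig = regularize_frames(raw, cfg)
    if cfg.invert:
        sig = UniformSignal(sig.start_time, sig.rate, -sig.values)
    filtered = bandpass_filter(sig, cfg)
    # Degenerate (near-constant) recordings leave only numerical residue in
    # the pass band; report no beats instead of residue extrema.
    if np.ptp(filtered.values) <= 1e-9 * max(1.0, float(np.max(np.abs(sig.values)))):
        return PeakSet(np.empty(0), np.empty(0, dtype=np.intp), np.empty(0))
    smoothed = smooth(filtered, cfg)
    resampled = resample_cubic_spline(smoothed, cfg)
    peaks = detect_local_maxima(resampled)
    after_global = prominence_filter_global(peaks, cfg)
    after_window = prominence_filter_window(after_global, cfg)
    t0 = resampled.start_time
    t1 = resampled.times[-1]
    guarded = after_window.take(
        (after_window.peak_times >= t0 + cfg.edge_guard_s)
        & (after_window.peak_times <= t1 - cfg.edge_guard_s))
    log.info(
        "ppg peaks: %d raw maxima -> %d after global filter -> %d after window "
        "filter -> %d after edge guard",
        len(peaks), len(after_global), len(after_window), len(guarded))
    return guarded
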