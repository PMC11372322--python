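"""Synthetic paired ECG/PPG recordings with known ground truth.

Emulates a ~5-minute seated smartphone-PPG recording taken alongside a
500 Hz reference ECG: beat-to-beat intervals carry respiratory sinus
arrhythmia plus white variability, the ECG is a train of narrow R
spikes with optional P/T bumps, and the camera luminosity shows an
asymmetric systolic pulse (as a dip — absorption convention) arriving
one pulse-transit delay after each R-wave, a dicrotic bump, slow
baseline drift, sensor noise and optional timestamp jitter. Every
generator is deterministic under its seed and returns the ground-truth
beat times and interval labels needed to score the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .types import FrameSeries, InvalidInputError, UniformSignal

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SubjectRecording",
    "generate_rr_series",
    "synthesize_ecg",
    "synthesize_ppg",
    "inject_artifacts",
    "simulate_cohort",
]

CLEAN = "clean"
ARTIFACT_KINDS = ("merged", "split", "spike")


@dataclass
class SimConfig:
    """Recording-level simulation parameters.

    Defaults match a healthy resting adult: mean R-R 857 ms (70 bpm)
    and SDNN near 73 ms, split between a 0.25 Hz respiratory
    modulation, a slower 0.1 Hz (Mayer-wave-like) oscillation and
    autocorrelated beat-to-beat noise; a 250 ms pulse-transit delay;
    and a dicrotic bump at 40% of systolic prominence 250 ms after the
    systolic apex. The noise is AR(1) rather than white because real
    R-R series are strongly autocorrelated — at SDNN 73 ms a white
    series would have a beat-to-beat RMSSD near 100 ms, far outside
    resting physiology.
    """

    duration_s: float = 300.0
    mean_rr_ms: float = 857.0
    rr_noise_sd_ms: float = 25.0
    rr_noise_ar: float = 0.8
    rsa_amplitude_ms: float = 50.0
    rsa_freq_hz: float = 0.25
    lf_amplitude_ms: float = 82.0
    lf_freq_hz: float = 0.1
    ecg_rate_hz: float = 500.0
    ppg_rate_hz: float = 30.0
    transit_delay_ms: float = 250.0
    dicrotic_rel_amplitude: float = 0.4
    dicrotic_delay_s: float = 0.25
    ppg_noise_sd: float = 0.02     # luminosity units; pulse amplitude is 1
    drift_amplitude: float = 0.5
    drift_freq_hz: float = 0.05
    artifact_fraction: float = 0.0
    seed: int = 0
    # morphology / nuisance knobs
    ecg_noise_sd: float = 0.0
    include_pt_waves: bool = True
    ppg_time_jitter_s: float = 0.0
    pulse_rise_sd_s: float = 0.08
    pulse_fall_sd_s: float = 0.08
    dicrotic_sd_s: float = 0.05
    first_beat_s: float = 1.2

    def __post_init__(self):
        if self.duration_s <= 0:
            raise InvalidInputError("duration_s must be positive")
        if not (300 < self.mean_rr_ms < 3000):
            raise InvalidInputError("mean_rr_ms must lie in (300, 3000)")
        if not (0 <= self.artifact_fraction < 1):
            raise InvalidInputError("artifact_fraction must lie in [0, 1)")
        if not (0 <= self.dicrotic_rel_amplitude < 1):
            raise InvalidInputError("dicrotic_rel_amplitude must lie in [0, 1)")


@dataclass
class GroundTruth:
    """True beat structure of one simulated recording.

    ``ecg_beat_times_s`` has one more entry than ``rr_ms``; successive
    differences of the beat times equal the intervals exactly.
    ``artifact_flags`` labels each interval ``clean`` or by the
    artifact kind applied to it.
    """

    rr_ms: np.ndarray
    ecg_beat_times_s: np.ndarray
    ppg_peak_times_s: np.ndarray
    artifact_flags: np.ndarray = field(default=None)
    #: one extra "supporter" beat synthesized after the last true beat
    #: (waveform only, never counted): under the 0.75-3 Hz band limit a
    #: stopped rhythm leaves its final beat with a truncated prominence,
    #: so the supporter restores normal two-sided support; it falls
    #: inside the extraction pipeline's boundary guard and is discarded
    support_beat_time_s: float = None
    #: where the synthesized record ends (shortly after the supporter)
    record_end_s: float = None

    def __post_init__(self):
        if self.artifact_flags is None:
            self.artifact_flags = np.full(len(self.rr_ms), CLEAN, dtype=object)
        d = np.diff(self.ecg_beat_times_s) * 1000.0
        if len(d) != len(self.rr_ms) or np.max(np.abs(d - self.rr_ms)) > 1e-6:
            raise InvalidInputError("beat times inconsistent with rr_ms")

    @property
    def n_beats(self) -> int:
        return len(self.ecg_beat_times_s)


@dataclass
class SubjectRecording:
    """One simulated participant: raw PPG, reference ECG, ground truth."""

    ppg: FrameSeries
    ecg: UniformSignal
    truth: GroundTruth
    config: SimConfig


def generate_rr_series(cfg: SimConfig) -> GroundTruth:
    """Beat times and R-R intervals with RSA plus slower variability.

    ``RR_i = mean_rr + A_rsa sin(2 pi f_rsa t_i)
    + A_lf sin(2 pi f_lf t_i + phi) + eps_i`` where ``eps`` is an
    AR(1) process with marginal SD ``rr_noise_sd_ms`` and lag-one
    correlation ``rr_noise_ar``; intervals are truncated to
    (300, 3000) ms and beat times are the cumulative sums starting at
    ``first_beat_s``. The slow-phase offset ``phi`` is drawn from the
    seed so subjects are not breath-locked to each other.

    One supporter beat (not part of the ground truth) continues the
    rhythm past the last true beat, and the record ends shortly after
    it; both the supporter and any boundary transients land inside the
    extraction pipeline's edge guard.
    """
    rng = np.random.default_rng(cfg.seed)
    phi = rng.uniform(0, 2 * np.pi)
    innov_sd = cfg.rr_noise_sd_ms * np.sqrt(max(1.0 - cfg.rr_noise_ar**2, 0.0))
    eps = rng.normal(0.0, cfg.rr_noise_sd_ms) if cfg.rr_noise_sd_ms > 0 else 0.0
    t = cfg.first_beat_s
    beat_times = [t]
    rr = []
    while True:
        interval = (cfg.mean_rr_ms
                    + cfg.rsa_amplitude_ms * np.sin(2 * np.pi * cfg.rsa_freq_hz * t)
                    + cfg.lf_amplitude_ms * np.sin(2 * np.pi * cfg.lf_freq_hz * t + phi)
                    + eps)
        eps = cfg.rr_noise_ar * eps + rng.normal(0.0, innov_sd) if cfg.rr_noise_sd_ms > 0 else 0.0
        interval = float(np.clip(interval, 300.0 + 1e-9, 3000.0 - 1e-9))
        nxt = t + interval / 1000.0
        if nxt > cfg.duration_s - 1.0:
            next_rr = interval
            break
        rr.append(interval)
        beat_times.append(nxt)
        t = nxt
    if len(rr) < 2:
        raise InvalidInputError("configuration yields fewer than 2 beats")
    beats = np.asarray(beat_times)
    support = beats[-1] + next_rr / 1000.0
    delay = cfg.transit_delay_ms / 1000.0
    return GroundTruth(np.asarray(rr), beats, beats + delay,
                       support_beat_time_s=float(support),
                       record_end_s=float(support + delay + 0.5))


def _add_bumps(values: np.ndarray, rate: float, centers: np.ndarray,
               amplitudes, sd_left: float, sd_right: float | None = None) -> None:
    """Accumulate (possibly asymmetric) Gaussian bumps in place."""
    sd_right = sd_left if sd_right is None else sd_right
    amplitudes = np.broadcast_to(np.asarray(amplitudes, dtype=float), centers.shape)
    half = 5.0 * max(sd_left, sd_right)
    n = len(values)
    for c, a in zip(centers, amplitudes):
        lo = max(0, int(np.floor((c - half) * rate)))
        hi = min(n, int(np.ceil((c + half) * rate)) + 1)
        if lo >= hi:
            continue
        tau = np.arange(lo, hi) / rate - c
        sd = np.where(tau < 0, sd_left, sd_right)
        values[lo:hi] += a * np.exp(-0.5 * (tau / sd) ** 2)


def _eval_bumps(values: np.ndarray, times: np.ndarray, centers: np.ndarray,
                amplitudes, sd_left: float, sd_right: float | None = None) -> None:
    """Accumulate bumps evaluated at arbitrary (sorted) sample times."""
    sd_right = sd_left if sd_right is None else sd_right
    amplitudes = np.broadcast_to(np.asarray(amplitudes, dtype=float), centers.shape)
    half = 5.0 * max(sd_left, sd_right)
    for c, a in zip(centers, amplitudes):
        lo = np.searchsorted(times, c - half)
        hi = np.searchsorted(times, c + half)
        if lo >= hi:
            continue
        tau = times[lo:hi] - c
        sd = np.where(tau < 0, sd_left, sd_right)
        values[lo:hi] += a * np.exp(-0.5 * (tau / sd) ** 2)


def synthesize_ecg(gt: GroundTruth, cfg: SimConfig) -> UniformSignal:
    """Reference ECG: narrow R spikes at beat times, optional P/T bumps, noise."""
    end = gt.record_end_s if gt.record_end_s is not None else cfg.duration_s
    n = int(round(end * cfg.ecg_rate_hz)) + 1
    values = np.zeros(n)
    beats = gt.ecg_beat_times_s
    if gt.support_beat_time_s is not None:
        beats = np.append(beats, gt.support_beat_time_s)
    _add_bumps(values, cfg.ecg_rate_hz, beats, 1.0, 0.010)
    if cfg.include_pt_waves:
        _add_bumps(values, cfg.ecg_rate_hz, beats - 0.16, 0.12, 0.025)
        _add_bumps(values, cfg.ecg_rate_hz, beats + 0.25, 0.20, 0.050)
    if cfg.ecg_noise_sd > 0:
        rng = np.random.default_rng((cfg.seed * 1_000_003 + 1) % (2**63))
        values += rng.normal(0.0, cfg.ecg_noise_sd, n)
    return UniformSignal(0.0, cfg.ecg_rate_hz, values)


def synthesize_ppg(gt: GroundTruth, cfg: SimConfig) -> FrameSeries:
    """Camera luminosity at the frame rate, systole as a dip.

    Each beat contributes a systolic bump peaking at beat time +
    transit delay, and a dicrotic bump ``dicrotic_delay_s`` later
    (systolic timing is nearly load-independent, so the delay is fixed
    rather than proportional to the local R-R) with
    ``dicrotic_rel_amplitude`` of the systolic height. The bump train
    is *subtracted* from a constant
    luminosity baseline (more blood absorbs more light), then slow
    sinusoidal drift, Gaussian sensor noise and optional timestamp
    jitter are applied.
    """
    rng = np.random.default_rng((cfg.seed * 1_000_003 + 2) % (2**63))
    end = gt.record_end_s if gt.record_end_s is not None else cfg.duration_s
    n_frames = int(np.floor(end * cfg.ppg_rate_hz)) + 1
    frame_times = np.arange(n_frames) / cfg.ppg_rate_hz
    if cfg.ppg_time_jitter_s > 0:
        jitter = rng.uniform(-cfg.ppg_time_jitter_s, cfg.ppg_time_jitter_s, n_frames)
        jitter[0] = 0.0
        frame_times = np.maximum.accumulate(frame_times + jitter)
        frame_times += np.arange(n_frames) * 1e-9   # enforce strict increase

    pulse = np.zeros(n_frames)
    systole = gt.ppg_peak_times_s
    if gt.support_beat_time_s is not None:
        delay = gt.ppg_peak_times_s[0] - gt.ecg_beat_times_s[0]
        systole = np.append(systole, gt.support_beat_time_s + delay)
    _eval_bumps(pulse, frame_times, systole, 1.0,
                cfg.pulse_rise_sd_s, cfg.pulse_fall_sd_s)
    if cfg.dicrotic_rel_amplitude > 0:
        _eval_bumps(pulse, frame_times, systole + cfg.dicrotic_delay_s,
                    cfg.dicrotic_rel_amplitude, cfg.dicrotic_sd_s)
    luminosity = 100.0 - pulse
    luminosity += cfg.drift_amplitude * np.sin(2 * np.pi * cfg.drift_freq_hz * frame_times)
    if cfg.ppg_noise_sd > 0:
        luminosity += rng.normal(0.0, cfg.ppg_noise_sd, n_frames)
    return FrameSeries(frame_times, luminosity, nominal_rate=cfg.ppg_rate_hz)


def inject_artifacts(gt: GroundTruth, cfg: SimConfig) -> GroundTruth:
    """Corrupt a seeded fraction of intervals with detection-style errors.

    Each selected interval suffers one of: *merged* (a missed beat — the
    interval absorbs its successor), *split* (a double detection — the
    interval is cut in two), or *spike* (scaled by 0.4 or 2.5). Beat
    times are rebuilt from the corrupted intervals, so the ground-truth
    consistency invariant still holds; affected intervals are labelled.
    """
    if cfg.artifact_fraction == 0:
        return gt
    rng = np.random.default_rng((cfg.seed * 1_000_003 + 3) % (2**63))
    rr = list(gt.rr_ms)
    flags = list(gt.artifact_flags)
    n_target = rng.binomial(len(rr), cfg.artifact_fraction)
    chosen = rng.choice(len(rr), size=min(n_target, len(rr)), replace=False)
    # apply right-to-left so merges/splits do not disturb pending indices
    for i in sorted(chosen, reverse=True):
        kind = ARTIFACT_KINDS[rng.integers(len(ARTIFACT_KINDS))]
        if kind == "merged" and i + 1 < len(rr) and flags[i + 1] == CLEAN:
            rr[i] = rr[i] + rr[i + 1]
            del rr[i + 1], flags[i + 1]
            flags[i] = "merged"
        elif kind == "split":
            frac = rng.uniform(0.4, 0.6)
            first = rr[i] * frac
            rr[i:i + 1] = [first, rr[i] - first]
            flags[i:i + 1] = ["split", "split"]
        else:
            rr[i] = rr[i] * (0.4 if rng.random() < 0.5 else 2.5)
            flags[i] = "spike"
    rr_arr = np.asarray(rr)
    beats = gt.ecg_beat_times_s[0] + np.concatenate([[0.0], np.cumsum(rr_arr) / 1000.0])
    delay = gt.ppg_peak_times_s[0] - gt.ecg_beat_times_s[0]
    # keep the same post-rhythm geometry after any shift of the last beat
    shift = beats[-1] - gt.ecg_beat_times_s[-1]
    support = (None if gt.support_beat_time_s is None
               else float(gt.support_beat_time_s + shift))
    record_end = (None if gt.record_end_s is None
                  else float(gt.record_end_s + shift))
    return GroundTruth(rr_arr, beats, beats + delay,
                       np.asarray(flags, dtype=object),
                       support_beat_time_s=support, record_end_s=record_end)


def simulate_cohort(n_subjects: int, cfg: SimConfig | None = None,
                    seed: int | None = None,
                    mean_rr_range_ms: tuple[float, float] = (679.0, 1020.0),
                    sdnn_mean_ms: float = 73.0,
                    sdnn_sd_ms: float = 22.0) -> list[SubjectRecording]:
    """Simulate a cohort of paired recordings with per-subject physiology.

    Per-subject mean R-R is drawn uniformly over the resting range
    observed in healthy young adults (about 59-88 bpm); the SDNN target
    is normal around 73 ms (floored at 25 ms) and split between RSA,
    the slow oscillation and AR(1) noise in the default proportion.
    """
    if n_subjects < 2:
        raise InvalidInputError("cohort needs at least 2 subjects")
    base = cfg or SimConfig()
    master_seed = base.seed if seed is None else seed
    rng = np.random.default_rng(master_seed)
    subjects = []
    for i in range(n_subjects):
        mean_rr = rng.uniform(*mean_rr_range_ms)
        sdnn_target = max(25.0, rng.normal(sdnn_mean_ms, sdnn_sd_ms))
        # scale all three variability components to the SDNN target,
        # keeping the default proportions
        default_sdnn = np.sqrt(base.rsa_amplitude_ms**2 / 2
                               + base.lf_amplitude_ms**2 / 2
                               + base.rr_noise_sd_ms**2)
        scale = sdnn_target / default_sdnn
        sub_cfg = replace(
            base,
            mean_rr_ms=float(mean_rr),
            rsa_amplitude_ms=float(base.rsa_amplitude_ms * scale),
            lf_amplitude_ms=float(base.lf_amplitude_ms * scale),
            rr_noise_sd_ms=float(base.rr_noise_sd_ms * scale),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        truth = inject_artifacts(generate_rr_series(sub_cfg), sub_cfg)
        subjects.append(SubjectRecording(
            ppg=synthesize_ppg(truth, sub_cfg),
            ecg=synthesize_ecg(truth, sub_cfg),
            truth=truth,
            config=sub_cfg,
        ))
    return subjects
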