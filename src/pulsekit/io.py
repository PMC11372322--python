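"""CSV/JSON readers and writers for recordings, peaks and intervals."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import FrameSeries, IntervalSeries, InvalidInputError, PeakSet, UniformSignal

__all__ = [
    "ParseError",
    "read_ppg_csv", "write_ppg_csv",
    "read_ecg_csv", "write_ecg_csv",
    "write_signal_csv",
    "read_intervals_csv", "write_intervals_csv",
    "write_peaks_csv",
    "write_pairs_csv", "read_pairs_csv",
    "write_json", "file_digest",
]


class ParseError(ValueError):
    """Raised when an input file cannot be parsed as expected."""


def _read_two_columns(path, col_a: str, col_b: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    missing = {col_a, col_b} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required column(s) {sorted(missing)}")
    for col in (col_a, col_b):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ParseError(f"{path}: non-numeric value in column {col!r}, "
                             f"row {int(bad[0]) + 2}")
    return df


def read_ppg_csv(path, nominal_rate: float = 30.0) -> FrameSeries:
    """Read a `time_s,luminosity` CSV into a :class:`FrameSeries`."""
    df = _read_two_columns(path, "time_s", "luminosity")
    try:
        return FrameSeries(df["time_s"].to_numpy(float),
                           df["luminosity"].to_numpy(float),
                           nominal_rate=nominal_rate)
    except InvalidInputError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_ppg_csv(path, series: FrameSeries) -> None:
    pd.DataFrame({"time_s": series.times, "luminosity": series.values}
                 ).to_csv(path, index=False)


def read_ecg_csv(path) -> UniformSignal:
    """Read a `time_s,voltage` CSV (uniformly sampled) into a :class:`UniformSignal`."""
    df = _read_two_columns(path, "time_s", "voltage")
    t = df["time_s"].to_numpy(float)
    if len(t) < 2:
        raise ParseError(f"{path}: need at least 2 samples")
    steps = np.diff(t)
    if steps.min() <= 0 or np.ptp(steps) > 0.01 * steps.mean():
        raise ParseError(f"{path}: time_s is not uniformly sampled")
    rate = 1.0 / steps.mean()
    return UniformSignal(float(t[0]), float(rate), df["voltage"].to_numpy(float))


def write_ecg_csv(path, sig: UniformSignal) -> None:
    pd.DataFrame({"time_s": sig.times, "voltage": sig.values}).to_csv(path, index=False)


def write_signal_csv(path, sig: UniformSignal) -> None:
    pd.DataFrame({"time_s": sig.times, "value": sig.values}).to_csv(path, index=False)


def write_peaks_csv(path, peaks: PeakSet, time_column: str = "r_time_s") -> None:
    pd.DataFrame({time_column: peaks.peak_times}).to_csv(path, index=False)


def write_intervals_csv(path, series: IntervalSeries) -> None:
    pd.DataFrame({
        "beat_time_s": series.beat_times,
        "interval_ms": series.intervals,
        "status": series.status,
    }).to_csv(path, index=False)


def read_intervals_csv(path) -> IntervalSeries:
    df = _read_two_columns(path, "beat_time_s", "interval_ms")
    if "status" not in df.columns:
        raise ParseError(f"{path}: missing required column(s) ['status']")
    try:
        return IntervalSeries(df["beat_time_s"].to_numpy(float),
                              df["interval_ms"].to_numpy(float),
                              df["status"].to_numpy(object))
    except InvalidInputError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_pairs_csv(path, pairing) -> None:
    pd.DataFrame({
        "ecg_beat_time_s": pairing.ecg_beat_times,
        "ecg_interval_ms": pairing.ecg_intervals,
        "ppg_interval_ms": pairing.ppg_intervals,
    }).to_csv(path, index=False)


def read_pairs_csv(path) -> pd.DataFrame:
    df = _read_two_columns(path, "ecg_interval_ms", "ppg_interval_ms")
    return df


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def file_digest(path) -> str:
    """SHA-256 of a file, for run manifests."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
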