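"""Accelerometer preprocessing and walking-bout segmentation.

The chain is: zero-phase Butterworth band-pass (0.5–20 Hz) on each axis →
step-peak detection on the vertical axis (height ≥ 0.5 m/s², separation
≥ fs/2 samples) → grouping of consecutive peaks into bouts (inter-peak gap
≤ 2.5 s), gated on ≥ 30 peaks and a mean co-occurring GPS speed < 5 km/h to
drop vehicle travel.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .geo import geodesic_km
from .stays import Trajectory

__all__ = [
    "AccelSignal",
    "WalkingBout",
    "SpeedSeries",
    "bandpass",
    "detect_peaks",
    "gps_speed_series",
    "segment_bouts",
    "read_accel_csv",
    "write_accel_csv",
]


@dataclass
class AccelSignal:
    """Triaxial trunk acceleration: vertical (vt), mediolateral (ml),
    anteroposterior (ap), in m/s² at sampling rate ``fs``; ``t0`` is the UTC
    epoch time of sample 0."""

    subject_id: str
    fs: float
    t0: float
    vt: np.ndarray
    ml: np.ndarray
    ap: np.ndarray

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.vt = np.asarray(self.vt, dtype=float)
        self.ml = np.asarray(self.ml, dtype=float)
        self.ap = np.asarray(self.ap, dtype=float)
        if not (self.vt.shape == self.ml.shape == self.ap.shape) or self.vt.ndim != 1:
            raise ValueError("vt, ml, ap must be 1-D arrays of equal length")

    def __len__(self) -> int:
        return self.vt.size

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.fs


@dataclass
class WalkingBout:
    """A qualifying walking episode; sample indices are half-open [start, end)."""

    start: int
    end: int
    peak_indices: np.ndarray
    mean_gps_speed_kmh: float = 0.0

    def __post_init__(self):
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)

    @property
    def n_peaks(self) -> int:
        return self.peak_indices.size

    def duration_s(self, fs: float) -> float:
        return (self.end - self.start) / fs

    def peak_times(self, fs: float, t0: float = 0.0) -> np.ndarray:
        return t0 + self.peak_indices / fs


from functools import lru_cache


@lru_cache(maxsize=32)
def _butter_sos(order: int, low: float, high: float, fs: float) -> np.ndarray:
    return sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass(
    x: np.ndarray, fs: float, low: float = 0.5, high: float = 20.0, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (filtfilt; ``order`` poles per pass)."""
    if not (0.0 < low < high < fs / 2.0):
        raise ValueError(
            f"band edges ({low}, {high}) must satisfy 0 < low < high < fs/2 = {fs / 2}"
        )
    sos = _butter_sos(order, float(low), float(high), float(fs))
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def bandpass_signal(sig: AccelSignal, low: float = 0.5, high: float = 20.0, order: int = 4) -> AccelSignal:
    return AccelSignal(
        subject_id=sig.subject_id,
        fs=sig.fs,
        t0=sig.t0,
        vt=bandpass(sig.vt, sig.fs, low, high, order),
        ml=bandpass(sig.ml, sig.fs, low, high, order),
        ap=bandpass(sig.ap, sig.fs, low, high, order),
    )


def detect_peaks(x: np.ndarray, fs: float, min_height: float = 0.5) -> np.ndarray:
    """Step-peak indices on a filtered vertical axis.

    Local maxima of value ≥ ``min_height`` with pairwise separation of at
    least fs/2 samples; of two conflicting candidates the higher one wins
    (scipy's distance rule).
    """
    distance = max(int(math.ceil(fs / 2.0)), 1)
    peaks, _ = sps.find_peaks(np.asarray(x, dtype=float), height=min_height, distance=distance)
    return peaks


@dataclass
class SpeedSeries:
    """Per-GPS-interval speeds (km/h); ``t`` marks interval midpoints."""

    t: np.ndarray
    speed_kmh: np.ndarray

    def at(self, times) -> np.ndarray:
        """Nearest-interval speed lookup for arbitrary timestamps."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        idx = np.clip(np.searchsorted(self.t, times), 0, len(self.t) - 1)
        left = np.clip(idx - 1, 0, len(self.t) - 1)
        use_left = np.abs(times - self.t[left]) <= np.abs(self.t[idx] - times)
        return self.speed_kmh[np.where(use_left, left, idx)]

    def mean_over(self, t_start: float, t_end: float) -> float:
        # pad by one GPS interval so windows shorter than the GPS spacing
        # still average a few intervals rather than trusting a single one
        pad = float(np.median(np.diff(self.t))) if self.t.size > 1 else 0.0
        inside = (self.t >= t_start - pad) & (self.t <= t_end + pad)
        if not inside.any():
            return float(self.at((t_start + t_end) / 2.0)[0])
        return float(np.mean(self.speed_kmh[inside]))


def gps_speed_series(traj: Trajectory) -> SpeedSeries:
    """Consecutive-fix geodesic speed per GPS interval, in km/h."""
    dt = np.diff(traj.t)
    good = dt > 0
    if not good.all():
        warnings.warn("zero time gap between fixes; interval skipped")
    d = geodesic_km(traj.lat[:-1], traj.lon[:-1], traj.lat[1:], traj.lon[1:])
    speed = np.asarray(d)[good] / (dt[good] / 3600.0)
    mid = (traj.t[:-1] + traj.t[1:])[good] / 2.0
    return SpeedSeries(t=mid, speed_kmh=speed)


def segment_bouts(
    peaks: np.ndarray,
    fs: float,
    t0: float = 0.0,
    speed: SpeedSeries | None = None,
    min_peaks: int = 30,
    max_speed_kmh: float = 5.0,
    max_gap_s: float = 2.5,
) -> list[WalkingBout]:
    """Group consecutive peaks into qualifying walking bouts.

    Peaks are split wherever the inter-peak gap exceeds ``max_gap_s``
    (continuity rule); each maximal run is kept iff it holds at least
    ``min_peaks`` peaks and the mean GPS speed over its enclosing window is
    below ``max_speed_kmh``. With no speed series the speed gate passes
    (speed treated as 0, i.e. on foot).
    """
    peaks = np.asarray(peaks, dtype=int)
    if peaks.size == 0:
        return []
    gaps = np.diff(peaks) / fs
    cut = np.nonzero(gaps > max_gap_s)[0] + 1
    bouts: list[WalkingBout] = []
    for run in np.split(peaks, cut):
        if run.size < min_peaks:
            continue
        t_start = t0 + run[0] / fs
        t_end = t0 + run[-1] / fs
        v = speed.mean_over(t_start, t_end) if speed is not None else 0.0
        if v >= max_speed_kmh:
            continue
        bouts.append(
            WalkingBout(start=int(run[0]), end=int(run[-1]) + 1, peak_indices=run, mean_gps_speed_kmh=v)
        )
    return bouts


# ---------------------------------------------------------------------------
# CSV dialect: subject_id,t,vt,ml,ap (t in epoch seconds, accel in m/s²)


def read_accel_csv(path: str | Path) -> AccelSignal:
    import pandas as pd

    df = pd.read_csv(path)
    required = {"subject_id", "t", "vt", "ml", "ap"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    t = df["t"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError(f"{path}: sample times not strictly increasing")
    fs = 1.0 / float(np.median(dt))
    return AccelSignal(
        subject_id=str(df["subject_id"].iloc[0]),
        fs=round(fs, 6),
        t0=float(t[0]),
        vt=df["vt"].to_numpy(dtype=float),
        ml=df["ml"].to_numpy(dtype=float),
        ap=df["ap"].to_numpy(dtype=float),
    )


def write_accel_csv(sig: AccelSignal, path: str | Path) -> None:
    t = sig.times()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "t", "vt", "ml", "ap"])
        for i in range(len(sig)):
            w.writerow(
                [sig.subject_id, f"{t[i]:.4f}", f"{sig.vt[i]:.6f}", f"{sig.ml[i]:.6f}", f"{sig.ap[i]:.6f}"]
            )
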