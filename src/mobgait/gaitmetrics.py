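"""Per-bout gait metrics and their per-subject aggregation.

Every temporal metric derives from the step-peak times of a qualifying
walking bout; spectral and signal metrics (RMS, harmonic ratio, entropy,
stride regularity) are computed on the band-passed axis slices of the bout
window. Per-subject values are the unweighted mean over qualifying bouts,
except step counts (summed) and walking speed (total steps × fixed step
length / total bout time).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields

import numpy as np
from scipy import signal as sps

from .bouts import AccelSignal, WalkingBout

__all__ = [
    "GaitFeatures",
    "step_times",
    "mean_step_time",
    "step_time_cv",
    "step_regularity",
    "step_symmetry",
    "stride_regularity",
    "walking_speed",
    "rms",
    "harmonic_ratio",
    "entropy",
    "compute_gait_features",
    "GAIT_FEATURE_COLUMNS",
    "DEFAULT_STEP_LENGTH_M",
]

DEFAULT_STEP_LENGTH_M = 0.7
REGULARITY_CAP = 1e6
HR_CAP = 1e6


@dataclass
class GaitFeatures:
    subject_id: str
    n_steps: float
    mean_step_time_s: float
    step_time_cv: float
    step_regularity: float
    stride_regularity: float
    step_symmetry: float
    walking_speed_mps: float
    rms_vt: float
    rms_ml: float
    rms_ap: float
    hr_vt: float
    hr_ml: float
    hr_ap: float
    entropy_vt: float
    entropy_ml: float
    entropy_ap: float

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


GAIT_FEATURE_COLUMNS = [f.name for f in fields(GaitFeatures) if f.name != "subject_id"]


def step_times(peak_times_s: np.ndarray) -> np.ndarray:
    """Consecutive inter-peak intervals in seconds."""
    peak_times_s = np.asarray(peak_times_s, dtype=float)
    if peak_times_s.size < 2:
        warnings.warn("fewer than 2 peaks: no step intervals")
        return np.empty(0)
    return np.diff(peak_times_s)


def mean_step_time(intervals: np.ndarray) -> float:
    intervals = np.asarray(intervals, dtype=float)
    if intervals.size == 0:
        return float("nan")
    return float(np.mean(intervals))


def step_time_cv(intervals: np.ndarray) -> float:
    """Coefficient of variation σ_T / T_mean (population SD)."""
    intervals = np.asarray(intervals, dtype=float)
    if intervals.size < 2:
        return float("nan")
    mu = np.mean(intervals)
    if mu == 0:
        raise ValueError("zero mean step time")
    return float(np.std(intervals) / mu)


def step_regularity(intervals: np.ndarray, cap: float = REGULARITY_CAP) -> float:
    """1 / σ_T (1/s), capped when the step times are (near-)constant."""
    intervals = np.asarray(intervals, dtype=float)
    if intervals.size < 2:
        return float("nan")
    sd = float(np.std(intervals))
    if sd < 1e-6:
        return cap
    return min(1.0 / sd, cap)


def step_symmetry(intervals: np.ndarray) -> float:
    """1 − (1/(N−1)) Σ |T_{i+1} − T_i| / T_mean; equals 1 iff all intervals
    are identical."""
    intervals = np.asarray(intervals, dtype=float)
    if intervals.size < 2:
        return float("nan")
    mu = np.mean(intervals)
    if mu == 0:
        raise ValueError("zero mean step time")
    return float(1.0 - np.mean(np.abs(np.diff(intervals))) / mu)


def stride_regularity(filtered_vt: np.ndarray, fs: float, mean_step_time_s: float) -> float:
    """Normalized unbiased autocorrelation of the vertical signal at the
    stride lag (two mean step times), clipped to [−1, 1]."""
    x = np.asarray(filtered_vt, dtype=float)
    lag = int(round(2.0 * mean_step_time_s * fs))
    if lag <= 0 or lag >= x.size:
        return float("nan")
    x = x - x.mean()
    var = float(np.mean(x**2))
    if var < 1e-18:
        return float("nan")
    c = float(np.dot(x[:-lag], x[lag:])) / (x.size - lag)
    return float(np.clip(c / var, -1.0, 1.0))


def walking_speed(
    n_steps: float, total_bout_time_s: float, step_length_m: float = DEFAULT_STEP_LENGTH_M
) -> float:
    """v = N_steps × L_step / T_total, with T_total the summed duration of
    qualifying bouts."""
    if total_bout_time_s <= 0:
        raise ValueError("total bout time must be positive")
    return n_steps * step_length_m / total_bout_time_s


def rms(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    return float(np.sqrt(np.mean(x**2)))


def harmonic_ratio(
    x: np.ndarray,
    fs: float,
    stride_frequency: float,
    n_harmonics: int = 20,
    cap: float = HR_CAP,
) -> float:
    """Even:odd spectral energy ratio at multiples of the stride frequency.

    Energies are squared magnitudes at harmonics 1..``n_harmonics`` of
    ``stride_frequency`` taken from a Hann-windowed periodogram by
    nearest-bin lookup (harmonics above Nyquist are dropped). A vanishing
    odd-energy sum caps the ratio at ``cap``.
    """
    x = np.asarray(x, dtype=float)
    if stride_frequency <= 0:
        return float("nan")
    freqs, power = sps.periodogram(x, fs=fs, window="hann")
    even = odd = 0.0
    for k in range(1, n_harmonics + 1):
        fk = k * stride_frequency
        if fk > freqs[-1]:
            break
        idx = int(np.argmin(np.abs(freqs - fk)))
        if k % 2 == 0:
            even += power[idx]
        else:
            odd += power[idx]
    if odd <= even / cap:
        return cap
    return float(even / odd)


def entropy(x: np.ndarray, n_bins: int = 32) -> float:
    """Shannon entropy (nats) of the equal-width histogram over [min, max].

    A constant signal occupies a single bin and has zero entropy.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    lo, hi = float(np.min(x)), float(np.max(x))
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / x.size
    return float(-np.sum(p * np.log(p)))


def _nan_row(subject_id: str) -> GaitFeatures:
    vals = {name: float("nan") for name in GAIT_FEATURE_COLUMNS}
    vals["n_steps"] = 0.0
    return GaitFeatures(subject_id=subject_id, **vals)


def compute_gait_features(
    filtered: AccelSignal,
    bouts: list[WalkingBout],
    step_length_m: float = DEFAULT_STEP_LENGTH_M,
    n_bins: int = 32,
) -> GaitFeatures:
    """Aggregate per-bout metrics into one subject row.

    ``filtered`` must already be band-passed. With no qualifying bout the
    row is all-missing (NaN) apart from a zero step count.
    """
    if not bouts:
        return _nan_row(filtered.subject_id)

    fs = filtered.fs
    per_bout: list[dict] = []
    total_steps = 0
    total_time = 0.0
    for b in bouts:
        pt = b.peak_indices / fs
        iv = step_times(pt)
        tm = mean_step_time(iv)
        stride_freq = 1.0 / (2.0 * tm) if tm > 0 else float("nan")
        sl = slice(b.start, b.end)
        per_bout.append(
            {
                "mean_step_time_s": tm,
                "step_time_cv": step_time_cv(iv),
                "step_regularity": step_regularity(iv),
                "stride_regularity": stride_regularity(filtered.vt[sl], fs, tm),
                "step_symmetry": step_symmetry(iv),
                "rms_vt": rms(filtered.vt[sl]),
                "rms_ml": rms(filtered.ml[sl]),
                "rms_ap": rms(filtered.ap[sl]),
                "hr_vt": harmonic_ratio(filtered.vt[sl], fs, stride_freq),
                "hr_ml": harmonic_ratio(filtered.ml[sl], fs, stride_freq),
                "hr_ap": harmonic_ratio(filtered.ap[sl], fs, stride_freq),
                "entropy_vt": entropy(filtered.vt[sl], n_bins),
                "entropy_ml": entropy(filtered.ml[sl], n_bins),
                "entropy_ap": entropy(filtered.ap[sl], n_bins),
            }
        )
        total_steps += b.n_peaks
        total_time += b.duration_s(fs)

    agg = {
        key: float(np.nanmean([pb[key] for pb in per_bout])) for key in per_bout[0]
    }
    return GaitFeatures(
        subject_id=filtered.subject_id,
        n_steps=float(total_steps),
        walking_speed_mps=walking_speed(total_steps, total_time, step_length_m),
        **agg,
    )
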