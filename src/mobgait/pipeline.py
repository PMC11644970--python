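"""End-to-end feature extraction: raw streams → per-subject feature rows.

This is the single interchange point between generation/ingestion on one
side and statistics/classification on the other: one row per subject with
the group label, the GPS life-space metrics and the gait metrics.
"""

from __future__ import annotations

import pandas as pd

from .bouts import AccelSignal, bandpass_signal, detect_peaks, gps_speed_series, segment_bouts
from .gaitmetrics import GaitFeatures, compute_gait_features
from .lifespace import GpsFeatures, compute_gps_features
from .stays import Trajectory, cluster_stays, detect_home, detect_stays
from .synth import Cohort

__all__ = [
    "extract_gps_row",
    "extract_gait_row",
    "extract_cohort_features",
]


def extract_gps_row(
    traj: Trajectory,
    spatial_radius_km: float = 0.1,
    min_stop_minutes: float = 15.0,
    cluster_eps_km: float = 0.1,
    cluster_min_samples: int = 1,
) -> GpsFeatures:
    """Stays → clusters → home → life-space features for one subject."""
    table = detect_stays(traj, spatial_radius_km, min_stop_minutes)
    if table.stays:
        table = cluster_stays(table, cluster_eps_km, cluster_min_samples)
        try:
            table = detect_home(table)
        except ValueError:
            pass
    return compute_gps_features(traj, table)


def extract_gait_row(
    accel: AccelSignal,
    traj: Trajectory | None = None,
    min_peaks: int = 30,
    max_speed_kmh: float = 5.0,
) -> GaitFeatures:
    """Filter → peaks → bout gating → gait features for one subject."""
    filtered = bandpass_signal(accel)
    peaks = detect_peaks(filtered.vt, filtered.fs)
    speed = gps_speed_series(traj) if traj is not None else None
    bouts = segment_bouts(
        peaks, filtered.fs, t0=filtered.t0, speed=speed,
        min_peaks=min_peaks, max_speed_kmh=max_speed_kmh,
    )
    return compute_gait_features(filtered, bouts)


def extract_cohort_features(cohort: Cohort, use_gps_speed: bool = True) -> pd.DataFrame:
    """One feature row per subject (group label + GPS + gait columns)."""
    rows = []
    for s in cohort.subjects:
        gps = extract_gps_row(s.trajectory)
        gait = extract_gait_row(s.accel, s.trajectory if use_gps_speed else None)
        row = {"subject_id": s.subject_id, "group": s.group}
        row.update({k: v for k, v in gps.to_dict().items() if k != "subject_id"})
        row.update({k: v for k, v in gait.to_dict().items() if k != "subject_id"})
        rows.append(row)
    return pd.DataFrame(rows)
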