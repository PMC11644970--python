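"""The GPS life-space metrics: activity space, compactness, visited places,
time outside home, maximum distance, straight-line path length, turning
radius, and radius of dispersion about home.

Areas/perimeters and turning angles are computed in a local planar
projection (km); all point-to-point distances are WGS84 geodesics. The
activity-space field serves both the "activity space" and "minimum convex
polygon" notions, which share the same area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

from .geo import LocalProjection, geodesic_km
from .stays import NOISE, StayTable, Trajectory

__all__ = [
    "GpsFeatures",
    "project_local",
    "mcp_area",
    "mcp_perimeter",
    "sde_compactness",
    "n_visited_places",
    "time_outside_home",
    "max_distance",
    "straight_line_distance",
    "turning_radius",
    "k_radius_of_gyration",
    "compute_gps_features",
    "GPS_FEATURE_COLUMNS",
]


@dataclass
class GpsFeatures:
    subject_id: str
    activity_space_km2: float
    sde_compactness: float
    n_visited_places: float
    time_outside_h: float
    max_distance_km: float
    straight_line_km: float
    turning_radius_km: float
    k_radius_gyration_km: float

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


GPS_FEATURE_COLUMNS = [f.name for f in fields(GpsFeatures) if f.name != "subject_id"]


def project_local(lats, lons) -> tuple[np.ndarray, np.ndarray, LocalProjection]:
    """Project fixes to planar (x, y) km about their centroid."""
    proj = LocalProjection.around_centroid(lats, lons)
    x, y = proj.forward(np.asarray(lats, dtype=float), np.asarray(lons, dtype=float))
    return x, y, proj


def _hull_vertices(x: np.ndarray, y: np.ndarray) -> np.ndarray | None:
    """Convex hull vertices in counter-clockwise order, or None if degenerate."""
    from scipy.spatial import ConvexHull
    from scipy.spatial._qhull import QhullError

    pts = np.column_stack([x, y])
    if len(pts) < 3:
        return None
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return None  # collinear / degenerate input
    return pts[hull.vertices]


def _shoelace(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return 0.5 * abs(float(np.sum(x * yn - xn * y)))


def mcp_area(x: np.ndarray, y: np.ndarray) -> float:
    """Minimum-convex-polygon (convex hull) area in km², shoelace on the
    closed hull. Degenerate clouds (<3 points or collinear) yield 0."""
    v = _hull_vertices(np.asarray(x, float), np.asarray(y, float))
    if v is None:
        return 0.0
    return _shoelace(v)


def mcp_perimeter(x: np.ndarray, y: np.ndarray) -> float:
    v = _hull_vertices(np.asarray(x, float), np.asarray(y, float))
    if v is None:
        return 0.0
    d = np.diff(np.vstack([v, v[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def sde_compactness(x: np.ndarray, y: np.ndarray) -> float:
    """4π·A_SDE / P_MCP² with A_SDE the area of the 1-SD standard
    deviational ellipse (principal-axis population SDs, area π·σ1·σ2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    P = mcp_perimeter(x, y)
    if P == 0.0:
        return 0.0
    xy = np.column_stack([x - x.mean(), y - y.mean()])
    cov = xy.T @ xy / len(xy)  # population covariance
    eigvals = np.linalg.eigvalsh(cov)
    if np.any(eigvals < 0):
        eigvals = np.clip(eigvals, 0.0, None)
    a_sde = math.pi * math.sqrt(eigvals[0]) * math.sqrt(eigvals[1])
    return 4.0 * math.pi * a_sde / P**2


def n_visited_places(stay_table: StayTable, include_home: bool = False) -> int:
    """Number of distinct non-noise stay clusters, excluding home by default."""
    clusters = {s.cluster_id for s in stay_table.stays if s.cluster_id != NOISE}
    if not include_home and stay_table.home_cluster is not None:
        clusters.discard(stay_table.home_cluster)
    return len(clusters)


def time_outside_home(stay_table: StayTable, traj: Trajectory) -> float:
    """Hours outside home: trajectory span minus cumulative home dwell."""
    if stay_table.home_cluster is None:
        raise ValueError("home cluster required to compute time outside home")
    home_dwell = sum(s.duration_s for s in stay_table.home_stays())
    return max(traj.span_s - home_dwell, 0.0) / 3600.0


def max_distance(traj: Trajectory, home: tuple[float, float]) -> float:
    """Maximum geodesic distance (km) from home over all fixes."""
    d = geodesic_km(home[0], home[1], traj.lat, traj.lon)
    return float(np.max(d))


def straight_line_distance(traj: Trajectory) -> float:
    """Cumulative consecutive geodesic path length (km)."""
    d = geodesic_km(traj.lat[:-1], traj.lon[:-1], traj.lat[1:], traj.lon[1:])
    return float(np.sum(d))


def turning_radius(traj: Trajectory, min_sin: float = 1e-9) -> float:
    """Mean per-triplet circumradius (km) over consecutive fix triplets.

    For each (P_i, P_{i+1}, P_{i+2}) the radius is l / (2 sin θ) with l the
    chord between the outer points and θ the turning angle at the middle one
    — the law-of-sines circumradius of the triplet. Triplets with a
    degenerate angle or repeated points are skipped; NaN if none survive.
    """
    x, y, _ = project_local(traj.lat, traj.lon)
    if len(x) < 3:
        return float("nan")
    ux, uy = np.diff(x), np.diff(y)  # segment vectors
    v1x, v1y = ux[:-1], uy[:-1]
    v2x, v2y = ux[1:], uy[1:]
    n1 = np.hypot(v1x, v1y)
    n2 = np.hypot(v2x, v2y)
    with np.errstate(divide="ignore", invalid="ignore"):
        sin_theta = np.abs(v1x * v2y - v1y * v2x) / (n1 * n2)
    chord = np.hypot(x[2:] - x[:-2], y[2:] - y[:-2])
    ok = (n1 > 0) & (n2 > 0) & (sin_theta >= min_sin)
    if not ok.any():
        return float("nan")
    return float(np.mean(chord[ok] / (2.0 * sin_theta[ok])))


def k_radius_of_gyration(
    traj: Trajectory, home: tuple[float, float], conventional: bool = False
) -> float:
    """Dispersion of per-fix geodesic distances to home (km).

    Default is the population SD of the distances, √(1/n Σ (dᵢ − d̄)²).
    ``conventional=True`` instead returns the RMS distance √(1/n Σ dᵢ²),
    the textbook radius of gyration about the reference point.
    """
    d = np.atleast_1d(geodesic_km(home[0], home[1], traj.lat, traj.lon))
    if conventional:
        return float(np.sqrt(np.mean(d**2)))
    return float(np.std(d))  # ddof=0


def compute_gps_features(traj: Trajectory, stay_table: StayTable) -> GpsFeatures:
    """Assemble the full life-space feature row for one subject.

    Undefined members (degenerate geometry, missing home) come back as NaN
    so downstream imputation can handle them.
    """
    x, y, _ = project_local(traj.lat, traj.lon)
    try:
        home = stay_table.home_location()
        t_out = time_outside_home(stay_table, traj)
        d_max = max_distance(traj, home)
        r_g = k_radius_of_gyration(traj, home)
        n_pl = float(n_visited_places(stay_table))
    except ValueError:
        home = None
        t_out = d_max = r_g = n_pl = float("nan")
    return GpsFeatures(
        subject_id=traj.subject_id,
        activity_space_km2=mcp_area(x, y),
        sde_compactness=sde_compactness(x, y),
        n_visited_places=n_pl,
        time_outside_h=t_out,
        max_distance_km=d_max,
        straight_line_km=straight_line_distance(traj),
        turning_radius_km=turning_radius(traj),
        k_radius_gyration_km=r_g,
    )
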