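"""Trajectory ingestion, stay detection, location clustering and home detection.

A *stay* is a maximal run of consecutive GPS fixes that remain within a
spatial radius (default 100 m) of the run's incremental centroid for at least
a minimum duration (default 15 min). Stays are then density-clustered
(DBSCAN on geodesic distance) into visited places, and the cluster with the
largest cumulative dwell time is taken as home.
"""

from __future__ import annotations

import csv
import io
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .geo import geodesic_km

NOISE = -1  # DBSCAN noise marker for stays not reaching cluster density

__all__ = [
    "Trajectory",
    "Stay",
    "StayTable",
    "read_trajectory",
    "write_trajectory_csv",
    "write_trajectory_gpx",
    "detect_stays",
    "cluster_stays",
    "detect_home",
    "write_stay_csv",
    "NOISE",
]


@dataclass(frozen=True)
class Trajectory:
    """Time-ordered GPS fixes for one subject-day.

    ``t`` holds UTC epoch seconds, strictly increasing.
    """

    subject_id: str
    t: np.ndarray
    lat: np.ndarray
    lon: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        lat = np.asarray(self.lat, dtype=float)
        lon = np.asarray(self.lon, dtype=float)
        if not (t.shape == lat.shape == lon.shape) or t.ndim != 1:
            raise ValueError("t, lat, lon must be 1-D arrays of equal length")
        if t.size < 2:
            raise ValueError(f"trajectory {self.subject_id!r}: fewer than 2 fixes")
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"trajectory {self.subject_id!r}: timestamps not strictly increasing")
        if np.any((lat < -90) | (lat > 90)):
            raise ValueError(f"trajectory {self.subject_id!r}: latitude outside [-90, 90]")
        if np.any((lon < -180) | (lon > 180)):
            raise ValueError(f"trajectory {self.subject_id!r}: longitude outside [-180, 180]")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "lat", lat)
        object.__setattr__(self, "lon", lon)

    def __len__(self) -> int:
        return self.t.size

    @property
    def span_s(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class Stay:
    """One dwell episode; the time interval is half-open [arrival, departure)."""

    centroid_lat: float
    centroid_lon: float
    arrival: float
    departure: float
    cluster_id: int = NOISE

    @property
    def duration_s(self) -> float:
        return self.departure - self.arrival


@dataclass
class StayTable:
    subject_id: str
    stays: list[Stay] = field(default_factory=list)
    home_cluster: int | None = None

    def __len__(self) -> int:
        return len(self.stays)

    def home_stays(self) -> list[Stay]:
        if self.home_cluster is None:
            raise ValueError("home cluster has not been detected")
        return [s for s in self.stays if s.cluster_id == self.home_cluster]

    def home_location(self) -> tuple[float, float]:
        """Dwell-weighted centroid of the home-cluster stays (lat, lon)."""
        hs = self.home_stays()
        if not hs:
            raise ValueError("home cluster contains no stays")
        w = np.array([s.duration_s for s in hs])
        w = w / w.sum() if w.sum() > 0 else np.full(len(hs), 1.0 / len(hs))
        return (
            float(np.dot(w, [s.centroid_lat for s in hs])),
            float(np.dot(w, [s.centroid_lon for s in hs])),
        )


# ---------------------------------------------------------------------------
# ingestion


def _parse_timestamp(text: str) -> float:
    ts = text.strip()
    try:
        return float(ts)
    except ValueError:
        pass
    if ts.endswith("Z"):
        ts = ts[:-1] + "+00:00"
    dt = datetime.fromisoformat(ts)
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt.timestamp()


def read_trajectory(path: str | Path, dialect: str | None = None) -> Trajectory:
    """Read a trajectory from CSV (``subject_id,timestamp,lat,lon``) or GPX 1.1.

    Points are returned sorted by time; exact duplicate timestamps are
    rejected. ``dialect`` may force ``"csv"`` or ``"gpx"``; by default the
    file suffix decides.
    """
    path = Path(path)
    kind = dialect or ("gpx" if path.suffix.lower() == ".gpx" else "csv")
    if kind == "gpx":
        return _read_gpx(path)
    if kind != "csv":
        raise ValueError(f"unknown trajectory dialect {kind!r}")

    subject = None
    rows: list[tuple[float, float, float]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise ValueError(f"{path}: empty file")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                sid, ts, lat, lon = row[0], row[1], float(row[2]), float(row[3])
                t = _parse_timestamp(ts)
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: unparseable row at line {lineno}: {exc}") from exc
            if not (-90.0 <= lat <= 90.0):
                raise ValueError(f"{path}: latitude {lat} out of range at line {lineno}")
            if not (-180.0 <= lon <= 180.0):
                raise ValueError(f"{path}: longitude {lon} out of range at line {lineno}")
            if subject is None:
                subject = sid
            elif sid != subject:
                raise ValueError(f"{path}: multiple subject ids ({subject!r}, {sid!r})")
            rows.append((t, lat, lon))
    return _finalize(subject or path.stem, rows, str(path))


def _read_gpx(path: Path) -> Trajectory:
    ns = {"gpx": "http://www.topografix.com/GPX/1/1"}
    tree = ET.parse(path)
    root = tree.getroot()
    name_el = root.find(".//gpx:trk/gpx:name", ns)
    subject = name_el.text.strip() if name_el is not None and name_el.text else path.stem
    rows = []
    for pt in root.findall(".//gpx:trkpt", ns):
        lat = float(pt.get("lat"))
        lon = float(pt.get("lon"))
        time_el = pt.find("gpx:time", ns)
        if time_el is None or not time_el.text:
            raise ValueError(f"{path}: track point without <time>")
        rows.append((_parse_timestamp(time_el.text), lat, lon))
    return _finalize(subject, rows, str(path))


def _finalize(subject: str, rows: list[tuple[float, float, float]], origin: str) -> Trajectory:
    if len(rows) < 2:
        raise ValueError(f"{origin}: trajectory has fewer than 2 points")
    rows.sort(key=lambda r: r[0])
    t = np.array([r[0] for r in rows])
    if np.any(np.diff(t) == 0):
        raise ValueError(f"{origin}: duplicate timestamps")
    return Trajectory(
        subject_id=subject,
        t=t,
        lat=np.array([r[1] for r in rows]),
        lon=np.array([r[2] for r in rows]),
    )


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "timestamp", "lat", "lon"])
        for t, la, lo in zip(traj.t, traj.lat, traj.lon):
            iso = datetime.fromtimestamp(t, tz=timezone.utc).isoformat()
            w.writerow([traj.subject_id, iso, f"{la:.8f}", f"{lo:.8f}"])


def write_trajectory_gpx(traj: Trajectory, path: str | Path) -> None:
    buf = io.StringIO()
    buf.write('<?xml version="1.0" encoding="UTF-8"?>\n')
    buf.write('<gpx version="1.1" creator="mobgait" xmlns="http://www.topografix.com/GPX/1/1">\n')
    buf.write(f"  <trk><name>{traj.subject_id}</name><trkseg>\n")
    for t, la, lo in zip(traj.t, traj.lat, traj.lon):
        iso = datetime.fromtimestamp(t, tz=timezone.utc).isoformat().replace("+00:00", "Z")
        buf.write(f'    <trkpt lat="{la:.8f}" lon="{lo:.8f}"><time>{iso}</time></trkpt>\n')
    buf.write("  </trkseg></trk>\n</gpx>\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# stay detection


def detect_stays(
    traj: Trajectory,
    spatial_radius_km: float = 0.1,
    min_stop_minutes: float = 15.0,
) -> StayTable:
    """Incremental-centroid stay detection.

    Walk the fixes in time order, growing a candidate run while each new fix
    lies within ``spatial_radius_km`` of the run's running centroid. When a
    fix breaks the run, the run becomes a :class:`Stay` iff it lasted at
    least ``min_stop_minutes``; otherwise its fixes are travel. Cluster ids
    are left unset (``NOISE``).
    """
    if spatial_radius_km <= 0:
        raise ValueError("spatial_radius_km must be positive")
    if min_stop_minutes <= 0:
        raise ValueError("min_stop_minutes must be positive")

    # work in a local planar frame: at the ~100 m stay scale the planar and
    # geodesic distances agree to well below GPS noise, and this keeps the
    # incremental loop cheap
    from .geo import LocalProjection

    proj = LocalProjection.around_centroid(traj.lat, traj.lon)
    x, y = proj.forward(traj.lat, traj.lon)
    r2 = spatial_radius_km**2

    min_s = min_stop_minutes * 60.0
    stays: list[Stay] = []
    n = len(traj)
    i = 0
    while i < n:
        # seed a run at fix i, growing while fixes stay near the running centroid
        cx, cy = x[i], y[i]
        j = i + 1
        while j < n:
            if (x[j] - cx) ** 2 + (y[j] - cy) ** 2 > r2:
                break
            m = j - i + 1
            cx += (x[j] - cx) / m
            cy += (y[j] - cy) / m
            j += 1
        if j - i >= 2 and traj.t[j - 1] - traj.t[i] >= min_s:
            clat, clon = proj.inverse(cx, cy)
            stays.append(
                Stay(
                    centroid_lat=float(clat),
                    centroid_lon=float(clon),
                    arrival=float(traj.t[i]),
                    departure=float(traj.t[j - 1]),
                )
            )
            i = j
        else:
            i += 1
    return StayTable(subject_id=traj.subject_id, stays=stays)


# ---------------------------------------------------------------------------
# clustering & home


def cluster_stays(
    stay_table: StayTable,
    max_distance_km: float = 0.1,
    min_samples: int = 1,
) -> StayTable:
    """Label stays by DBSCAN on geodesic stay-centroid distances.

    Returns a new table whose stays carry cluster ids; stays not reaching
    ``min_samples`` density are labelled ``NOISE`` (-1). Labels are renumbered
    by earliest arrival within each cluster so the result is independent of
    input order.
    """
    if max_distance_km <= 0:
        raise ValueError("max_distance_km must be positive")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    if not stay_table.stays:
        raise ValueError("cannot cluster an empty stay table")

    from sklearn.cluster import DBSCAN

    lats = np.array([s.centroid_lat for s in stay_table.stays])
    lons = np.array([s.centroid_lon for s in stay_table.stays])
    dmat = geodesic_km(lats[:, None], lons[:, None], lats[None, :], lons[None, :])
    labels = DBSCAN(eps=max_distance_km, min_samples=min_samples, metric="precomputed").fit(
        np.asarray(dmat)
    ).labels_

    # renumber clusters by earliest arrival for order stability
    arrivals = np.array([s.arrival for s in stay_table.stays])
    order: dict[int, int] = {}
    for lbl in sorted(set(labels) - {NOISE}, key=lambda l: arrivals[labels == l].min()):
        order[lbl] = len(order)
    new_stays = [
        replace(s, cluster_id=order[l] if l != NOISE else NOISE)
        for s, l in zip(stay_table.stays, labels)
    ]
    return StayTable(subject_id=stay_table.subject_id, stays=new_stays)


def detect_home(stay_table: StayTable) -> StayTable:
    """Pick the home cluster: maximum cumulative dwell; ties go to the
    cluster with the earliest arrival. Returns a new table with
    ``home_cluster`` set."""
    dwell: dict[int, float] = {}
    first: dict[int, float] = {}
    for s in stay_table.stays:
        if s.cluster_id == NOISE:
            continue
        dwell[s.cluster_id] = dwell.get(s.cluster_id, 0.0) + s.duration_s
        first[s.cluster_id] = min(first.get(s.cluster_id, math.inf), s.arrival)
    if not dwell:
        raise ValueError(f"subject {stay_table.subject_id!r}: no clustered stays, cannot detect home")
    home = min(dwell, key=lambda c: (-dwell[c], first[c]))
    return StayTable(subject_id=stay_table.subject_id, stays=list(stay_table.stays), home_cluster=home)


def write_stay_csv(tables: Iterable[StayTable] | StayTable, path: str | Path) -> None:
    if isinstance(tables, StayTable):
        tables = [tables]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "cluster_id", "arrival_iso", "departure_iso", "lat", "lon"])
        for table in tables:
            for s in table.stays:
                w.writerow(
                    [
                        table.subject_id,
                        s.cluster_id,
                        datetime.fromtimestamp(s.arrival, tz=timezone.utc).isoformat(),
                        datetime.fromtimestamp(s.departure, tz=timezone.utc).isoformat(),
                        f"{s.centroid_lat:.8f}",
                        f"{s.centroid_lon:.8f}",
                    ]
                )
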