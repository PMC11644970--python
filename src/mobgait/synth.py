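"""Synthetic faller / non-faller cohorts with known ground truth.

Gait signals are built as phase-jittered sums of harmonics of the stride
fundamental f0 = 1/(2·T_mean): even stride harmonics (the step-frequency
family) are cosine-aligned so every step produces a vertical peak, while odd
harmonics — whose energy is set from ``even_odd_energy_ratio`` — carry
random phases. Step intervals are jittered with a clipped, re-standardized
normal so the realized population CV of each bout equals the profile CV
exactly. Trajectories are planned itineraries (community start → dwell
places → home) built in a local planar frame and inverted to WGS84, with a
small GPS scatter on every fix.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np

from .bouts import AccelSignal, write_accel_csv
from .geo import LocalProjection
from .stays import Trajectory, write_trajectory_csv

__all__ = [
    "GaitProfile",
    "MobilityProfile",
    "CohortSpec",
    "AccelTruth",
    "TrajectoryTruth",
    "Subject",
    "Cohort",
    "generate_accel_stream",
    "generate_trajectory",
    "generate_cohort",
    "reference_profiles",
    "compact_profiles",
    "write_cohort",
]

# harmonic amplitude templates (relative); keys are stride-harmonic numbers.
# On VT every harmonic is cosine-aligned to the step events, so derivatives
# vanish there and detected step times stay truthful. The VT odd amplitude is
# capped (_VT_ODD_DELTA_CAP) so the alternating peak-height perturbation can
# never push a step peak under the detection threshold; beyond the cap the
# vertical even:odd ratio saturates, and the group contrast in measured VT
# harmonic ratio is carried by ``noise_sd`` (broadband odd-bin energy) while
# ML/AP follow ``even_odd_energy_ratio`` exactly.
_VT_EVEN = {2: 1.0, 4: 0.45, 6: 0.2}
_VT_ODD = {3: 1.0}
_VT_ODD_DELTA_CAP = 0.22
_ML_EVEN = {2: 0.6, 4: 0.25}
_ML_ODD = {1: 0.5, 3: 0.6}
_AP_EVEN = {2: 0.8, 4: 0.3}
_AP_ODD = {1: 0.3, 3: 0.6, 5: 0.25}

GPS_SCATTER_KM = 0.008  # 1-sigma per-fix GPS noise
DWELL_JITTER_KM = 0.010  # extra scatter while dwelling (still << stay radius)


@dataclass(frozen=True)
class GaitProfile:
    """Generator-side truth for the gait chain."""

    mean_step_time: float  # s
    step_time_cv: float  # fraction
    step_amplitude: float = 1.0  # m/s², vertical peak scale
    even_odd_energy_ratio: float = 4.0
    asymmetry: float = 0.0  # alternate steps lengthened/shortened by this fraction
    noise_sd: float = 0.05  # m/s² white noise
    bout_count: int = 2
    bout_steps: int = 40

    def __post_init__(self):
        if self.mean_step_time <= 0:
            raise ValueError("mean_step_time must be positive")
        if self.step_time_cv < 0 or self.noise_sd < 0:
            raise ValueError("step_time_cv and noise_sd must be non-negative")
        if self.even_odd_energy_ratio <= 0:
            raise ValueError("even_odd_energy_ratio must be positive")
        if not (0 <= self.asymmetry < 0.5):
            raise ValueError("asymmetry must be in [0, 0.5)")
        if self.bout_count < 0 or self.bout_steps < 2:
            raise ValueError("bout_count >= 0 and bout_steps >= 2 required")


@dataclass(frozen=True)
class MobilityProfile:
    """Generator-side truth for the trajectory chain."""

    home: tuple[float, float] = (45.0, 7.0)  # lat, lon
    n_places: int = 3
    place_radius_km: float = 0.55
    dwell_minutes_mean: float = 20.0
    trip_speed_kmh: float = 3.8
    outside_hours: float = 1.63
    day_length_hours: float = 8.0

    def __post_init__(self):
        if self.n_places < 0:
            raise ValueError("n_places must be >= 0")
        if self.place_radius_km <= 0:
            raise ValueError("place_radius_km must be positive")
        if not (0 < self.outside_hours <= self.day_length_hours):
            raise ValueError("need 0 < outside_hours <= day_length_hours")
        if self.trip_speed_kmh <= 0:
            raise ValueError("trip_speed_kmh must be positive")


@dataclass(frozen=True)
class CohortSpec:
    n_per_group: int
    nonfaller_gait: GaitProfile
    faller_gait: GaitProfile
    nonfaller_mob: MobilityProfile
    faller_mob: MobilityProfile
    fs: float = 50.0
    gps_interval: float = 60.0
    seed: int = 0
    gait_jitter: float = 0.12  # lognormal sigma on per-subject gait parameters
    mob_jitter: float = 0.30  # lognormal sigma on per-subject mobility parameters
    n_nonfaller: int | None = None  # optional unbalanced override
    n_faller: int | None = None

    def __post_init__(self):
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.fs <= 40.0:
            raise ValueError("fs must exceed twice the 20 Hz band edge")

    @property
    def group_sizes(self) -> tuple[int, int]:
        return (
            self.n_nonfaller if self.n_nonfaller is not None else self.n_per_group,
            self.n_faller if self.n_faller is not None else self.n_per_group,
        )


# ---------------------------------------------------------------------------
# accelerometer stream


@dataclass
class AccelTruth:
    """Ground truth for one generated stream."""

    bout_windows: list[tuple[float, float]]  # (start_s, end_s) relative to t0
    step_times: list[np.ndarray]  # per bout, seconds relative to t0
    n_steps: int
    profile: GaitProfile


def _jittered_intervals(rng: np.random.Generator, n: int, mean: float, cv: float,
                        asymmetry: float) -> np.ndarray:
    """n intervals with exact sample mean ``mean`` and population CV ``cv``.

    Jitter is a clipped (±1.5σ), re-standardized normal so no interval can
    undershoot the fs/2 peak-separation rule even at cv = 0.08. Asymmetry
    alternately scales intervals by (1 ± a) afterwards.
    """
    if n < 1:
        return np.empty(0)
    if cv > 0 and n > 1:
        z = np.clip(rng.standard_normal(n), -1.5, 1.5)
        z = z - z.mean()
        sd = z.std()
        z = z / sd if sd > 0 else z
        iv = mean * (1.0 + cv * z)
    else:
        iv = np.full(n, mean)
    if asymmetry > 0:
        signs = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
        iv = iv * (1.0 + asymmetry * signs)
    return iv


def _axis_energy_scale(even: dict, odd: dict, ratio: float) -> float:
    """delta multiplying the odd template so even:odd energy equals ratio."""
    e_even = sum(a * a for a in even.values())
    e_odd = sum(a * a for a in odd.values())
    return float(np.sqrt(e_even / (ratio * e_odd)))


def _synth_axis(
    phase: np.ndarray,
    env: np.ndarray,
    even: dict,
    odd: dict,
    delta: float,
    amp_scale: float,
    odd_phases: dict,
    even_phases: dict | None = None,
) -> np.ndarray:
    out = np.zeros_like(phase)
    for k, a in even.items():
        psi = 0.0 if even_phases is None else even_phases[k]
        out += a * np.cos(k * phase + psi)
    for k, a in odd.items():
        out += delta * a * np.cos(k * phase + odd_phases[k])
    return amp_scale * env * out


def generate_accel_stream(
    profile: GaitProfile,
    fs: float = 50.0,
    duration: float | None = None,
    seed: int = 0,
    subject_id: str = "S",
    t0: float = 0.0,
    rest_gap_s: float = 6.0,
) -> tuple[AccelSignal, AccelTruth]:
    """Generate a triaxial stream holding ``bout_count`` walking bouts.

    ``duration=None`` sizes the stream to exactly fit the requested bouts
    plus rest gaps. An explicit duration too short for the request raises a
    capacity error. Identical arguments produce bit-identical output.
    """
    if fs < 50.0:
        raise ValueError("fs must be >= 50 Hz")
    rng = np.random.default_rng(seed)
    T = profile.mean_step_time
    ramp = 0.6 * T
    bout_len = (profile.bout_steps - 1) * T * (1.0 + 2.0 * profile.step_time_cv) + 2.0 * ramp
    needed = profile.bout_count * bout_len + (profile.bout_count + 1) * rest_gap_s
    if duration is None:
        duration = needed
    elif duration < needed:
        raise ValueError(
            f"duration {duration:.1f}s cannot hold {profile.bout_count} bouts of "
            f"{profile.bout_steps} steps (need >= {needed:.1f}s)"
        )

    n = int(round(duration * fs))
    tt = np.arange(n) / fs
    vt = np.zeros(n)
    ml = np.zeros(n)
    ap = np.zeros(n)

    free = duration - profile.bout_count * bout_len
    gap = free / (profile.bout_count + 1) if profile.bout_count else 0.0

    windows: list[tuple[float, float]] = []
    steps_per_bout: list[np.ndarray] = []
    delta_vt = min(
        _axis_energy_scale(_VT_EVEN, _VT_ODD, profile.even_odd_energy_ratio),
        _VT_ODD_DELTA_CAP,
    )
    delta_ml = _axis_energy_scale(_ML_EVEN, _ML_ODD, profile.even_odd_energy_ratio)
    delta_ap = _axis_energy_scale(_AP_EVEN, _AP_ODD, profile.even_odd_energy_ratio)
    peak_scale = profile.step_amplitude / sum(_VT_EVEN.values())

    cursor = gap
    for _ in range(profile.bout_count):
        iv = _jittered_intervals(
            rng, profile.bout_steps - 1, T, profile.step_time_cv, profile.asymmetry
        )
        # first peak on the sample grid so constant-cadence streams are exact
        first = round((cursor + ramp) * fs) / fs
        steps = first + np.concatenate([[0.0], np.cumsum(iv)])
        w0, w1 = steps[0] - ramp, steps[-1] + ramp
        windows.append((w0, w1))
        steps_per_bout.append(steps)

        i0 = max(int(np.floor(w0 * fs)), 0)
        i1 = min(int(np.ceil(w1 * fs)) + 1, n)
        seg_t = tt[i0:i1]

        # stride phase: pi per step, linearly interpolated, edge-extrapolated
        step_phase = np.pi * np.arange(len(steps))
        phase = np.interp(seg_t, steps, step_phase)
        lead = seg_t < steps[0]
        phase[lead] = (seg_t[lead] - steps[0]) * np.pi / iv[0] if len(iv) else 0.0
        trail = seg_t > steps[-1]
        if len(iv):
            phase[trail] = step_phase[-1] + (seg_t[trail] - steps[-1]) * np.pi / iv[-1]

        env = np.ones_like(seg_t)
        on = seg_t < steps[0]
        env[on] = 0.5 * (1.0 + np.cos(np.pi * (steps[0] - seg_t[on]) / ramp))
        off = seg_t > steps[-1]
        env[off] = 0.5 * (1.0 + np.cos(np.pi * (seg_t[off] - steps[-1]) / ramp))

        odd_vt = {k: 0.0 for k in _VT_ODD}  # aligned: height-only perturbation
        ph_ml_e = {k: rng.uniform(0, 2 * np.pi) for k in _ML_EVEN}
        odd_ml = {k: rng.uniform(0, 2 * np.pi) for k in _ML_ODD}
        ph_ap_e = {k: rng.uniform(0, 2 * np.pi) for k in _AP_EVEN}
        odd_ap = {k: rng.uniform(0, 2 * np.pi) for k in _AP_ODD}

        vt[i0:i1] += _synth_axis(phase, env, _VT_EVEN, _VT_ODD, delta_vt, peak_scale, odd_vt)
        ml[i0:i1] += _synth_axis(
            phase, env, _ML_EVEN, _ML_ODD, delta_ml, 0.8 * peak_scale, odd_ml, ph_ml_e
        )
        ap[i0:i1] += _synth_axis(
            phase, env, _AP_EVEN, _AP_ODD, delta_ap, 0.9 * peak_scale, odd_ap, ph_ap_e
        )
        cursor = w1 + gap

    if profile.noise_sd > 0:
        vt += rng.normal(0.0, profile.noise_sd, n)
        ml += rng.normal(0.0, profile.noise_sd, n)
        ap += rng.normal(0.0, profile.noise_sd, n)

    sig = AccelSignal(subject_id=subject_id, fs=fs, t0=t0, vt=vt, ml=ml, ap=ap)
    truth = AccelTruth(
        bout_windows=windows,
        step_times=steps_per_bout,
        n_steps=profile.bout_count * profile.bout_steps,
        profile=profile,
    )
    return sig, truth


# ---------------------------------------------------------------------------
# trajectory


@dataclass
class PlannedStay:
    lat: float
    lon: float
    arrival_s: float  # relative to t0
    departure_s: float
    is_home: bool = False


@dataclass
class TrajectoryTruth:
    home: tuple[float, float]
    stays: list[PlannedStay]
    outside_hours: float
    max_distance_km: float
    n_places: int
    profile: MobilityProfile


def _place_layout(
    rng: np.random.Generator, n_places: int, radius_km: float, min_sep_km: float = 0.35
) -> list[tuple[float, float]]:
    """Plan (x, y) km positions around home with a minimum pairwise and
    home separation, so each dwell collapses to its own stay/cluster."""
    places: list[tuple[float, float]] = []
    for _ in range(n_places):
        for _attempt in range(300):
            ang = rng.uniform(0, 2 * np.pi)
            r = radius_km * rng.uniform(0.6, 1.0)
            cand = (r * np.cos(ang), r * np.sin(ang))
            sep_ok = np.hypot(*cand) >= min_sep_km and all(
                np.hypot(cand[0] - p[0], cand[1] - p[1]) >= min_sep_km for p in places
            )
            if sep_ok:
                places.append(cand)
                break
        else:
            raise ValueError(
                f"cannot place {n_places} places >= {min_sep_km} km apart within "
                f"{radius_km} km of home; increase place_radius_km"
            )
    return places


def _wander_path(
    rng: np.random.Generator,
    start: tuple[float, float],
    target: tuple[float, float],
    slack_km: float,
    radius_km: float,
) -> list[tuple[float, float]]:
    """Waypoints from start to target whose total length exceeds the direct
    leg by ``slack_km`` (exactly), all within the neighborhood disc."""
    path = [start]
    remaining = slack_km
    while remaining > 1.8 * radius_km:
        last = path[-1]
        q = None
        for _ in range(100):
            ang = rng.uniform(0, 2 * np.pi)
            r = radius_km * rng.uniform(0.3, 1.0)
            cand = (r * np.cos(ang), r * np.sin(ang))
            added = (
                np.hypot(cand[0] - last[0], cand[1] - last[1])
                + np.hypot(target[0] - cand[0], target[1] - cand[1])
                - np.hypot(target[0] - last[0], target[1] - last[1])
            )
            if 0.05 * radius_km < added <= remaining:
                q = cand
                break
        if q is None:
            break
        path.append(q)
        remaining -= added
    if remaining > 1e-9:
        # perpendicular bump on the final leg sized to absorb the rest exactly
        last = path[-1]
        L = np.hypot(target[0] - last[0], target[1] - last[1])
        if L < 1e-9:
            # degenerate: out-and-back spur of half the remaining length
            ang = rng.uniform(0, 2 * np.pi)
            h = remaining / 2.0
            path.append((last[0] + h * np.cos(ang), last[1] + h * np.sin(ang)))
        else:
            h = float(np.sqrt(((remaining + L) / 2.0) ** 2 - (L / 2.0) ** 2))
            mx, my = (last[0] + target[0]) / 2.0, (last[1] + target[1]) / 2.0
            nx, ny = -(target[1] - last[1]) / L, (target[0] - last[0]) / L
            path.append((mx + h * nx, my + h * ny))
    return path[1:]


def generate_trajectory(
    profile: MobilityProfile,
    gps_interval: float = 60.0,
    seed: int = 0,
    subject_id: str = "S",
    t0: float = 0.0,
    strict: bool = True,
) -> tuple[Trajectory, TrajectoryTruth]:
    """Generate one subject-day of GPS fixes plus the ground-truth stay log.

    The day starts away from home (a community-center analogue inside the
    neighborhood), meanders toward the first dwell place so that the planned
    time outside home equals ``outside_hours`` exactly, visits ``n_places``
    dwell locations at ``trip_speed_kmh``, and ends with a home dwell
    filling the remaining day. With ``strict=False`` an infeasibly small
    ``outside_hours`` is clamped up to the itinerary minimum instead of
    raising; the truth log always records the realized plan.
    """
    rng = np.random.default_rng(seed)
    proj = LocalProjection(*profile.home)
    min_sep = min(0.35, max(0.25, profile.place_radius_km * 0.55))
    places = _place_layout(rng, profile.n_places, profile.place_radius_km, min_sep)

    dwells = [
        max(16.0 * 60.0, profile.dwell_minutes_mean * 60.0 * rng.uniform(0.85, 1.25))
        for _ in places
    ]
    speed_kms = profile.trip_speed_kmh / 3600.0  # km per second

    ang = rng.uniform(0, 2 * np.pi)
    r0 = profile.place_radius_km * rng.uniform(0.7, 1.0)
    start = (r0 * np.cos(ang), r0 * np.sin(ang))

    first_stop = places[0] if places else (0.0, 0.0)
    route = [start] + places + [(0.0, 0.0)]
    direct_travel = sum(
        np.hypot(route[i + 1][0] - route[i][0], route[i + 1][1] - route[i][1]) / speed_kms
        for i in range(len(route) - 1)
    )
    slack = profile.outside_hours * 3600.0 - sum(dwells) - direct_travel
    if slack < 0.0:
        if strict:
            raise ValueError(
                f"outside_hours={profile.outside_hours} cannot hold {profile.n_places} "
                f"dwells plus travel (need >= {(sum(dwells) + direct_travel) / 3600:.2f} h)"
            )
        slack = 0.0
    wander = _wander_path(rng, start, first_stop, slack * speed_kms, profile.place_radius_km)

    # waypoint schedule: (x, y, t_arrive, t_depart) in seconds from t0
    sched: list[tuple[float, float, float, float]] = [(start[0], start[1], 0.0, 0.0)]
    clock = 0.0
    pos = start
    stays: list[PlannedStay] = []
    for w in wander:
        clock += np.hypot(w[0] - pos[0], w[1] - pos[1]) / speed_kms
        sched.append((w[0], w[1], clock, clock))
        pos = w
    for (xy, dwell) in zip(places, dwells):
        clock += np.hypot(xy[0] - pos[0], xy[1] - pos[1]) / speed_kms
        sched.append((xy[0], xy[1], clock, clock + dwell))
        lat_p, lon_p = proj.inverse(xy[0], xy[1])
        stays.append(PlannedStay(float(lat_p), float(lon_p), clock, clock + dwell))
        clock += dwell
        pos = xy
    clock += np.hypot(pos[0], pos[1]) / speed_kms
    day_end = profile.day_length_hours * 3600.0
    if clock >= day_end:
        raise ValueError("itinerary exceeds day_length_hours")
    sched.append((0.0, 0.0, clock, day_end))
    stays.append(PlannedStay(profile.home[0], profile.home[1], clock, day_end, is_home=True))

    # sample fixes along the schedule
    times = np.arange(0.0, day_end + 1e-9, gps_interval)
    xs = np.empty_like(times)
    ys = np.empty_like(times)
    for i, t in enumerate(times):
        seg = None
        for j in range(len(sched)):
            xj, yj, ta, td = sched[j]
            if ta <= t <= td:
                seg = (xj, yj)
                break
            if j + 1 < len(sched) and td < t < sched[j + 1][2]:
                xn, yn, tn, _ = sched[j + 1]
                frac = (t - td) / (tn - td)
                seg = (xj + frac * (xn - xj), yj + frac * (yn - yj))
                break
        if seg is None:
            seg = (sched[-1][0], sched[-1][1])
        xs[i], ys[i] = seg

    dwelling = np.zeros(len(times), dtype=bool)
    for _, _, ta, td in sched[1:]:
        dwelling |= (times >= ta) & (times <= td)
    scatter = np.where(dwelling, DWELL_JITTER_KM, GPS_SCATTER_KM)
    xs = xs + rng.normal(0.0, 1.0, len(times)) * scatter
    ys = ys + rng.normal(0.0, 1.0, len(times)) * scatter

    lat, lon = proj.inverse(xs, ys)
    traj = Trajectory(subject_id=subject_id, t=t0 + times, lat=lat, lon=lon)

    d_way = [np.hypot(x, y) for (x, y, _, _) in sched]
    truth = TrajectoryTruth(
        home=profile.home,
        stays=[
            replace(s, arrival_s=s.arrival_s + t0, departure_s=s.departure_s + t0)
            for s in stays
        ],
        outside_hours=clock / 3600.0,
        max_distance_km=float(max(d_way)),
        n_places=profile.n_places,
        profile=profile,
    )
    return traj, truth


# ---------------------------------------------------------------------------
# cohort


@dataclass
class Subject:
    subject_id: str
    group: str  # "non_faller" | "faller"
    trajectory: Trajectory
    accel: AccelSignal
    traj_truth: TrajectoryTruth
    accel_truth: AccelTruth


@dataclass
class Cohort:
    spec: CohortSpec
    subjects: list[Subject] = field(default_factory=list)

    def truth_table(self):
        import pandas as pd

        rows = []
        for s in self.subjects:
            row = {"subject_id": s.subject_id, "group": s.group}
            for f in fields(GaitProfile):
                row[f"gait_{f.name}"] = getattr(s.accel_truth.profile, f.name)
            mp = s.traj_truth.profile
            for f in fields(MobilityProfile):
                if f.name == "home":
                    row["home_lat"], row["home_lon"] = mp.home
                else:
                    row[f"mob_{f.name}"] = getattr(mp, f.name)
            row["planned_outside_h"] = s.traj_truth.outside_hours
            row["planned_max_distance_km"] = s.traj_truth.max_distance_km
            row["n_steps_true"] = s.accel_truth.n_steps
            rows.append(row)
        return pd.DataFrame(rows)


def _lognorm(rng: np.random.Generator, base: float, sigma: float,
             lo: float | None = None, hi: float | None = None) -> float:
    v = base * float(np.exp(sigma * rng.standard_normal()))
    if lo is not None:
        v = max(v, lo)
    if hi is not None:
        v = min(v, hi)
    return v


def _subject_profiles(
    rng: np.random.Generator, gait: GaitProfile, mob: MobilityProfile,
    gait_sigma: float, mob_sigma: float,
) -> tuple[GaitProfile, MobilityProfile]:
    g = replace(
        gait,
        mean_step_time=_lognorm(rng, gait.mean_step_time, gait_sigma, lo=0.4, hi=2.5),
        step_time_cv=_lognorm(rng, gait.step_time_cv, 1.5 * gait_sigma, lo=1e-4, hi=0.12),
        step_amplitude=_lognorm(rng, gait.step_amplitude, gait_sigma, lo=0.9),
        even_odd_energy_ratio=_lognorm(rng, gait.even_odd_energy_ratio, 1.5 * gait_sigma, lo=2.0),
    )
    # scatter each home by a few km so cohort geometry is not shared
    dlat = rng.uniform(-0.02, 0.02)
    dlon = rng.uniform(-0.02, 0.02)
    radius = _lognorm(rng, mob.place_radius_km, mob_sigma, lo=0.3, hi=2.2 * mob.place_radius_km)
    dwell = _lognorm(rng, mob.dwell_minutes_mean, 0.5 * mob_sigma, lo=16.5, hi=40.0)
    # worst-case itinerary (all legs at the 2-radius bound) must fit the day
    budget = mob.day_length_hours - 0.3
    need = mob.n_places * dwell / 60.0 + 2.0 * radius * (mob.n_places + 1) / mob.trip_speed_kmh
    if need > budget:
        scale = budget / need
        dwell = max(16.5, dwell * scale)
        radius = max(0.3, radius * scale)
    # infeasibly small draws are clamped later by generate_trajectory(strict=False)
    outside = _lognorm(
        rng, mob.outside_hours, 0.6 * mob_sigma, hi=mob.day_length_hours - 0.25
    )
    m = replace(
        mob,
        home=(mob.home[0] + dlat, mob.home[1] + dlon),
        place_radius_km=radius,
        dwell_minutes_mean=dwell,
        outside_hours=outside,
    )
    return g, m


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the full two-group cohort of raw streams plus truth."""
    rng = np.random.default_rng(spec.seed)
    cohort = Cohort(spec=spec)
    n_nf, n_f = spec.group_sizes
    groups = [("non_faller", "nf", n_nf, spec.nonfaller_gait, spec.nonfaller_mob),
              ("faller", "fa", n_f, spec.faller_gait, spec.faller_mob)]
    for group, prefix, count, gait, mob in groups:
        for i in range(count):
            sid = f"{prefix}{i + 1:03d}"
            g, m = _subject_profiles(rng, gait, mob, spec.gait_jitter, spec.mob_jitter)
            seed_t = int(rng.integers(0, 2**31 - 1))
            seed_a = int(rng.integers(0, 2**31 - 1))
            traj, t_truth = generate_trajectory(
                m, gps_interval=spec.gps_interval, seed=seed_t, subject_id=sid, strict=False
            )
            accel, a_truth = generate_accel_stream(
                g, fs=spec.fs, seed=seed_a, subject_id=sid, t0=float(traj.t[0])
            )
            cohort.subjects.append(Subject(sid, group, traj, accel, t_truth, a_truth))
    return cohort


# ---------------------------------------------------------------------------
# presets


def reference_profiles() -> dict:
    """Full-day default profiles whose downstream group medians move in the
    directions reported for faller vs non-faller cohorts (slower, more
    variable, less harmonic gait; smaller activity space)."""
    return {
        "nonfaller_gait": GaitProfile(
            mean_step_time=0.73, step_time_cv=0.0301, step_amplitude=1.2,
            even_odd_energy_ratio=6.0, asymmetry=0.02, noise_sd=0.08,
            bout_count=4, bout_steps=60,
        ),
        "faller_gait": GaitProfile(
            mean_step_time=1.24, step_time_cv=0.0417, step_amplitude=1.4,
            even_odd_energy_ratio=3.0, asymmetry=0.04, noise_sd=0.16,
            bout_count=4, bout_steps=58,
        ),
        "nonfaller_mob": MobilityProfile(
            n_places=3, place_radius_km=0.55, dwell_minutes_mean=20.0,
            trip_speed_kmh=3.8, outside_hours=1.63, day_length_hours=8.0,
        ),
        "faller_mob": MobilityProfile(
            n_places=3, place_radius_km=0.42, dwell_minutes_mean=20.0,
            trip_speed_kmh=3.8, outside_hours=1.30, day_length_hours=8.0,
        ),
    }


def compact_profiles() -> dict:
    """Scaled-down profiles (short day, one bout) for fast simulation runs;
    same group contrasts as :func:`reference_profiles`."""
    ref = reference_profiles()
    return {
        "nonfaller_gait": replace(ref["nonfaller_gait"], bout_count=1, bout_steps=40),
        "faller_gait": replace(ref["faller_gait"], bout_count=1, bout_steps=38),
        "nonfaller_mob": replace(
            ref["nonfaller_mob"], n_places=2, dwell_minutes_mean=17.0,
            outside_hours=1.15, day_length_hours=2.0, place_radius_km=0.50,
        ),
        "faller_mob": replace(
            ref["faller_mob"], n_places=2, dwell_minutes_mean=17.0,
            outside_hours=0.95, day_length_hours=2.0, place_radius_km=0.40,
        ),
    }


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write per-subject trajectory and accelerometer CSVs plus truth.csv."""
    outdir = Path(outdir)
    (outdir / "gps").mkdir(parents=True, exist_ok=True)
    (outdir / "accel").mkdir(parents=True, exist_ok=True)
    for s in cohort.subjects:
        write_trajectory_csv(s.trajectory, outdir / "gps" / f"{s.subject_id}.csv")
        write_accel_csv(s.accel, outdir / "accel" / f"{s.subject_id}.csv")
    cohort.truth_table().to_csv(outdir / "truth.csv", index=False)
    with open(outdir / "labels.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "group"])
        for s in cohort.subjects:
            w.writerow([s.subject_id, s.group])
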