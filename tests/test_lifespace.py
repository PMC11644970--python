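import math

import numpy as np
import pytest

from mobgait.geo import geodesic_km
from mobgait.lifespace import (
    GPS_FEATURE_COLUMNS,
    compute_gps_features,
    k_radius_of_gyration,
    max_distance,
    mcp_area,
    mcp_perimeter,
    n_visited_places,
    project_local,
    sde_compactness,
    straight_line_distance,
    time_outside_home,
    turning_radius,
)
from mobgait.stays import Stay, StayTable, Trajectory, cluster_stays, detect_home, detect_stays

LAT0, LON0 = 45.0, 7.0


def traj_from_xy(xy_km, dt=60.0, sid="S"):
    """Build a Trajectory from planar offsets (km) around (LAT0, LON0)."""
    from mobgait.geo import LocalProjection

    proj = LocalProjection(LAT0, LON0)
    xy = np.asarray(xy_km, dtype=float)
    lat, lon = proj.inverse(xy[:, 0], xy[:, 1])
    return Trajectory(subject_id=sid, t=np.arange(len(xy)) * dt, lat=lat, lon=lon)


class TestProjection:
    def test_single_point_maps_to_origin(self):
        x, y, _ = project_local(np.array([45.0]), np.array([7.0]))
        assert x[0] == pytest.approx(0.0) and y[0] == pytest.approx(0.0)

    def test_latitude_step_separation(self):
        x, y, _ = project_local(np.array([45.0, 45.01]), np.array([7.0, 7.0]))
        sep = float(np.hypot(np.diff(x), np.diff(y))[0])
        oracle = geodesic_km(45.0, 7.0, 45.01, 7.0)
        assert sep == pytest.approx(oracle, rel=2e-4)

    def test_round_trip(self):
        lats = np.array([45.0, 45.02, 44.99])
        lons = np.array([7.0, 7.01, 6.98])
        x, y, proj = project_local(lats, lons)
        la, lo = proj.inverse(x, y)
        assert np.max(np.abs(la - lats)) < 1e-9
        assert np.max(np.abs(lo - lons)) < 1e-9


class TestMcpArea:
    def test_unit_square(self):
        x = np.array([0.0, 1.0, 1.0, 0.0])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        assert mcp_area(x, y) == pytest.approx(1.0, rel=1e-12)

    def test_collinear_zero(self):
        x = np.linspace(0, 5, 10)
        assert mcp_area(x, 2.0 * x) == 0.0

    def test_fewer_than_three_points(self):
        assert mcp_area(np.array([0.0, 1.0]), np.array([0.0, 1.0])) == 0.0

    def test_matches_triangle_fan_oracle(self):
        from scipy.spatial import ConvexHull

        rng = np.random.default_rng(12)
        x, y = rng.normal(size=(2, 200))
        got = mcp_area(x, y)
        # independent oracle: hull vertices + triangle fan about vertex 0
        hull = ConvexHull(np.column_stack([x, y]))
        v = np.column_stack([x, y])[hull.vertices]
        fan = 0.0
        for i in range(1, len(v) - 1):
            a, b = v[i] - v[0], v[i + 1] - v[0]
            fan += 0.5 * abs(a[0] * b[1] - a[1] * b[0])
        assert got == pytest.approx(fan, rel=1e-9)


class TestSdeCompactness:
    def test_isotropic_cloud_monte_carlo(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0.0, 2.0, size=(2, 100_000))
        got = sde_compactness(x, y)
        # ellipse area = pi * sigma1 * sigma2 over principal axes = pi*sqrt(det cov)
        xc = np.column_stack([x - x.mean(), y - y.mean()])
        cov = xc.T @ xc / len(xc)
        oracle = 4.0 * math.pi * (math.pi * math.sqrt(np.linalg.det(cov))) / mcp_perimeter(x, y) ** 2
        assert got == pytest.approx(oracle, rel=1e-9)
        # isotropic closed form with the common SD
        sigma = math.sqrt(np.std(x) * np.std(y))
        assert got == pytest.approx(
            4.0 * math.pi * math.pi * sigma**2 / mcp_perimeter(x, y) ** 2, rel=0.01
        )

    def test_identical_points_zero(self):
        assert sde_compactness(np.zeros(10), np.zeros(10)) == 0.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=(2, 300))
        a = sde_compactness(x, y)
        b = sde_compactness(2.0 * x, 2.0 * y)
        assert a == pytest.approx(b, rel=1e-9)


def _clustered_table(points, durations, arrivals=None):
    arrivals = arrivals or [i * 3600.0 for i in range(len(points))]
    stays = [
        Stay(centroid_lat=la, centroid_lon=lo, arrival=t0, departure=t0 + d)
        for (la, lo), d, t0 in zip(points, durations, arrivals)
    ]
    return detect_home(cluster_stays(StayTable("S", stays), 0.1, 1))


class TestStayDerivedMetrics:
    def test_home_only_zero_places(self):
        table = _clustered_table([(LAT0, LON0)], [6 * 3600.0])
        assert n_visited_places(table) == 0

    def test_three_places_plus_home(self):
        pts = [(LAT0, LON0), (LAT0 + 0.01, LON0), (LAT0 + 0.02, LON0), (LAT0, LON0 + 0.02)]
        table = _clustered_table(pts, [6 * 3600.0, 1200.0, 1200.0, 1200.0])
        assert n_visited_places(table) == 3
        assert n_visited_places(table, include_home=True) == 4

    def test_time_outside_complement(self):
        # 8 h span, 6.5 h home dwell -> 1.5 h outside
        table = _clustered_table([(LAT0, LON0)], [6.5 * 3600.0])
        traj = traj_from_xy(np.zeros((2, 2)), dt=8 * 3600.0)
        assert time_outside_home(table, traj) == pytest.approx(1.5)

    def test_never_leaves_home(self):
        table = _clustered_table([(LAT0, LON0)], [4 * 3600.0])
        traj = traj_from_xy(np.zeros((2, 2)), dt=4 * 3600.0)
        assert time_outside_home(table, traj) == pytest.approx(0.0)

    def test_no_home_raises(self):
        table = StayTable("S", [])
        traj = traj_from_xy(np.zeros((2, 2)))
        with pytest.raises(ValueError):
            time_outside_home(table, traj)

    def test_synthetic_outside_recovery(self):
        from mobgait.synth import MobilityProfile, generate_trajectory

        prof = MobilityProfile(outside_hours=1.63, day_length_hours=8.0)
        traj, truth = generate_trajectory(prof, gps_interval=60.0, seed=21)
        table = detect_home(cluster_stays(detect_stays(traj), 0.1, 1))
        got = time_outside_home(table, traj)
        assert abs(got - truth.outside_hours) <= 2.0 * 60.0 / 3600.0
        assert truth.outside_hours == pytest.approx(1.63, abs=1e-9)


class TestDistances:
    def test_max_distance_all_home(self):
        traj = traj_from_xy(np.zeros((5, 2)))
        assert max_distance(traj, (LAT0, LON0)) == pytest.approx(0.0, abs=1e-9)

    def test_max_distance_latitude_offset(self):
        traj = traj_from_xy(np.zeros((2, 2)))
        traj = Trajectory("S", traj.t, np.array([LAT0, LAT0 + 0.01]), np.array([LON0, LON0]))
        oracle = geodesic_km(LAT0, LON0, LAT0 + 0.01, LON0)
        assert max_distance(traj, (LAT0, LON0)) == pytest.approx(oracle, rel=1e-12)

    def test_max_monotone_under_closer_fix(self):
        xy = [(0, 0), (3, 0)]
        d1 = max_distance(traj_from_xy(xy), (LAT0, LON0))
        d2 = max_distance(traj_from_xy(xy + [(1, 0)]), (LAT0, LON0))
        assert d2 == pytest.approx(d1, rel=1e-9)

    def test_straight_line_two_fixes(self):
        traj = traj_from_xy([(0, 0), (1, 0)])
        assert straight_line_distance(traj) == pytest.approx(1.0, rel=1e-4)

    def test_out_and_back_counts_twice(self):
        traj = traj_from_xy([(0, 0), (1, 0), (0, 0)])
        assert straight_line_distance(traj) == pytest.approx(2.0, rel=1e-4)

    def test_random_walk_matches_pairwise_oracle(self):
        rng = np.random.default_rng(5)
        lat = LAT0 + rng.uniform(-0.05, 0.05, 80)
        lon = LON0 + rng.uniform(-0.05, 0.05, 80)
        traj = Trajectory("S", np.arange(80) * 60.0, lat, lon)
        got = straight_line_distance(traj)
        oracle = sum(
            geodesic_km(lat[i], lon[i], lat[i + 1], lon[i + 1]) for i in range(79)
        )
        assert got == pytest.approx(oracle, rel=1e-9)


class TestTurningRadius:
    def test_circle_recovered(self):
        theta = np.linspace(0, 1.5 * np.pi, 25)
        xy = np.column_stack([np.cos(theta), np.sin(theta)])  # radius 1 km
        assert turning_radius(traj_from_xy(xy)) == pytest.approx(1.0, rel=1e-3)

    def test_right_angle_thales(self):
        # legs of 1 km at a right angle: circumradius = hypotenuse/2 = sqrt(2)/2
        traj = traj_from_xy([(0, 0), (1, 0), (1, 1)])
        assert turning_radius(traj) == pytest.approx(math.sqrt(2) / 2, rel=1e-4)

    def test_straight_track_undefined(self):
        traj = traj_from_xy([(0, 0), (1, 0), (2, 0), (3, 0)])
        assert math.isnan(turning_radius(traj))


class TestRadiusOfGyration:
    def test_equidistant_fixes_zero(self):
        xy = [(1, 0), (0, 1), (-1, 0), (0, -1)]
        assert k_radius_of_gyration(traj_from_xy(xy), (LAT0, LON0)) == pytest.approx(
            0.0, abs=1e-6
        )

    def test_two_point_sd(self):
        xy = [(0, 0), (2, 0)]
        assert k_radius_of_gyration(traj_from_xy(xy), (LAT0, LON0)) == pytest.approx(
            1.0, rel=1e-4
        )

    def test_matches_brute_force_sd(self):
        rng = np.random.default_rng(6)
        lat = LAT0 + rng.uniform(-0.05, 0.05, 60)
        lon = LON0 + rng.uniform(-0.05, 0.05, 60)
        traj = Trajectory("S", np.arange(60) * 60.0, lat, lon)
        got = k_radius_of_gyration(traj, (LAT0, LON0))
        d = np.array([geodesic_km(LAT0, LON0, la, lo) for la, lo in zip(lat, lon)])
        oracle = math.sqrt(np.mean((d - d.mean()) ** 2))
        assert got == pytest.approx(oracle, rel=1e-12)

    def test_conventional_option(self):
        traj = traj_from_xy([(1, 0), (1, 0), (1, 0)])
        # printed form: SD of equal distances = 0; conventional: RMS distance = 1
        assert k_radius_of_gyration(traj, (LAT0, LON0)) == pytest.approx(0.0, abs=1e-6)
        assert k_radius_of_gyration(traj, (LAT0, LON0), conventional=True) == pytest.approx(
            1.0, rel=1e-3
        )


class TestComputeGpsFeatures:
    def test_stay_at_home_day(self):
        rng = np.random.default_rng(8)
        n = 120
        lat = LAT0 + rng.normal(0, 5e-5, n)  # ~5 m scatter
        lon = LON0 + rng.normal(0, 5e-5, n)
        traj = Trajectory("S", np.arange(n) * 60.0, lat, lon)
        table = detect_home(cluster_stays(detect_stays(traj), 0.1, 1))
        feats = compute_gps_features(traj, table)
        assert feats.n_visited_places == 0
        assert feats.activity_space_km2 < 2e-3  # GPS-scatter-sized hull only
        assert feats.max_distance_km < 0.05
        assert feats.time_outside_h == pytest.approx(0.0, abs=0.1)

    def test_schema_stable(self, small_features):
        assert GPS_FEATURE_COLUMNS == [
            "activity_space_km2",
            "sde_compactness",
            "n_visited_places",
            "time_outside_h",
            "max_distance_km",
            "straight_line_km",
            "turning_radius_km",
            "k_radius_gyration_km",
        ]
        for col in GPS_FEATURE_COLUMNS:
            assert col in small_features.columns

    def test_time_shift_invariance(self, basic_mobility):
        from mobgait.synth import generate_trajectory

        traj, _ = generate_trajectory(basic_mobility, seed=13)
        shifted = Trajectory(traj.subject_id, traj.t + 86400.0, traj.lat, traj.lon)
        f1 = compute_gps_features(traj, detect_home(cluster_stays(detect_stays(traj), 0.1, 1)))
        f2 = compute_gps_features(
            shifted, detect_home(cluster_stays(detect_stays(shifted), 0.1, 1))
        )
        for k, v in f1.to_dict().items():
            if k == "subject_id":
                continue
            assert v == pytest.approx(f2.to_dict()[k], rel=1e-9)

    def test_dmax_bounded_by_total_path_from_home(self, basic_mobility):
        from mobgait.synth import generate_trajectory

        traj, truth = generate_trajectory(basic_mobility, seed=17)
        # prepend a fix at home so the path starts there
        traj2 = Trajectory(
            "S",
            np.concatenate([[traj.t[0] - 60.0], traj.t]),
            np.concatenate([[truth.home[0]], traj.lat]),
            np.concatenate([[truth.home[1]], traj.lon]),
        )
        assert max_distance(traj2, truth.home) <= straight_line_distance(traj2) + 1e-9
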