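import numpy as np
import pytest

from mobgait.pipeline import extract_cohort_features
from mobgait.synth import CohortSpec, GaitProfile, MobilityProfile, compact_profiles, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """10-subject compact cohort shared by integration-level tests."""
    return generate_cohort(CohortSpec(n_per_group=5, seed=11, **compact_profiles()))


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return extract_cohort_features(small_cohort)


@pytest.fixture
def clean_gait_profile():
    """Noiseless constant-cadence profile: one bout, 40 steps at 1.0 s."""
    return GaitProfile(
        mean_step_time=1.0,
        step_time_cv=0.0,
        step_amplitude=1.0,
        even_odd_energy_ratio=1e9,
        asymmetry=0.0,
        noise_sd=0.0,
        bout_count=1,
        bout_steps=40,
    )


@pytest.fixture
def basic_mobility():
    return MobilityProfile(
        n_places=3,
        place_radius_km=0.6,
        dwell_minutes_mean=20.0,
        trip_speed_kmh=3.8,
        outside_hours=2.2,
        day_length_hours=6.0,
    )


def make_trajectory(subject_id="S", t=None, lat=None, lon=None):
    from mobgait.stays import Trajectory

    return Trajectory(
        subject_id=subject_id,
        t=np.asarray(t, dtype=float),
        lat=np.asarray(lat, dtype=float),
        lon=np.asarray(lon, dtype=float),
    )
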