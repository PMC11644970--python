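"""Shared helpers for the test suite (importable because pytest adds the
tests directory to sys.path via rootdir conftest)."""

import numpy as np
import pandas as pd

from mobgait.gaitmetrics import GAIT_FEATURE_COLUMNS
from mobgait.lifespace import GPS_FEATURE_COLUMNS

ALL_FEATURE_COLUMNS = list(GPS_FEATURE_COLUMNS) + list(GAIT_FEATURE_COLUMNS)


def separable_table(n_per_group=20, separation=10.0, seed=0, noisy_cols=None):
    """Gaussian feature table whose group means differ by ``separation`` SDs
    on every column except ``noisy_cols``."""
    rng = np.random.default_rng(seed)
    noisy_cols = set(noisy_cols or [])
    rows = {}
    for col in ALL_FEATURE_COLUMNS:
        shift = 0.0 if col in noisy_cols else separation
        rows[col] = np.concatenate(
            [rng.normal(0, 1, n_per_group), rng.normal(shift, 1, n_per_group)]
        )
    df = pd.DataFrame(rows)
    df.insert(0, "group", ["non_faller"] * n_per_group + ["faller"] * n_per_group)
    df.insert(0, "subject_id", [f"s{i}" for i in range(2 * n_per_group)])
    return df
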