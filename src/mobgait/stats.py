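"""Two-group non-parametric comparison of the cohort feature table.

Per variable: Shapiro–Wilk normality screen per group, Mann–Whitney U
(exact enumeration for small tie-free samples, tie-corrected normal
approximation otherwise), and median / IQR summaries. No multiple-testing
correction by default, with an optional Holm adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import stats as sst

__all__ = ["ComparisonRow", "normality_screen", "mann_whitney", "compare_all"]

EXACT_MAX_N = 12  # exact enumeration threshold (combined sample size)


@dataclass
class ComparisonRow:
    variable: str
    median_nonfaller: float
    iqr_nonfaller: float
    median_faller: float
    iqr_faller: float
    u_statistic: float
    p_value: float
    significant: bool

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def normality_screen(*groups) -> list[float]:
    """Shapiro–Wilk p-value per group; NaN marks a constant (undefined) sample."""
    out = []
    for g in groups:
        g = np.asarray(g, dtype=float)
        g = g[~np.isnan(g)]
        if g.size < 3 or np.ptp(g) == 0.0:
            out.append(float("nan"))
            continue
        out.append(float(sst.shapiro(g).pvalue))
    return out


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """(U of group_a, two-sided p).

    Exact for combined n ≤ 12 without ties; tie-corrected normal
    approximation otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if a.size + b.size <= EXACT_MAX_N and not has_ties:
        res = sst.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = sst.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def _iqr(x: np.ndarray) -> float:
    # linear-interpolation quartiles
    q1, q3 = np.percentile(x, [25, 75])
    return float(q3 - q1)


def compare_all(
    cohort: pd.DataFrame,
    alpha: float = 0.05,
    group_col: str = "group",
    faller_label: str = "faller",
    holm: bool = False,
) -> pd.DataFrame:
    """One comparison row per feature column; missing values dropped
    pairwise. Columns entirely missing in one group are skipped with a
    warning."""
    if group_col not in cohort.columns:
        raise ValueError(f"missing group column {group_col!r}")
    labels = cohort[group_col]
    is_faller = labels == faller_label
    if is_faller.sum() < 2 or (~is_faller).sum() < 2:
        raise ValueError("need at least 2 subjects per group")

    feature_cols = [
        c for c in cohort.columns
        if c not in (group_col, "subject_id") and pd.api.types.is_numeric_dtype(cohort[c])
    ]
    rows: list[ComparisonRow] = []
    for col in feature_cols:
        a = cohort.loc[~is_faller, col].dropna().to_numpy(dtype=float)  # non-faller
        b = cohort.loc[is_faller, col].dropna().to_numpy(dtype=float)
        if a.size == 0 or b.size == 0:
            warnings.warn(f"variable {col!r} entirely missing in one group; skipped")
            continue
        u, p = mann_whitney(a, b)
        rows.append(
            ComparisonRow(
                variable=col,
                median_nonfaller=float(np.median(a)),
                iqr_nonfaller=_iqr(a),
                median_faller=float(np.median(b)),
                iqr_faller=_iqr(b),
                u_statistic=u,
                p_value=p,
                significant=bool(p < alpha),
            )
        )
    df = pd.DataFrame([r.to_dict() for r in rows])
    if holm and len(df):
        order = np.argsort(df["p_value"].to_numpy())
        m = len(df)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * df["p_value"].iloc[idx])
            adj[idx] = min(running, 1.0)
        df["p_holm"] = adj
        df["significant"] = df["p_holm"] < alpha
    return df
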