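"""SUVR computation over late windows and window selection against DVR.

SUVR — the ratio of window-averaged target to reference activity — is a
cheap static surrogate for the dynamic DVR.  Its fidelity depends on the
acquisition window: too early and the tissue has not reached transient
equilibrium, too late and counts are poor.  This module computes SUVR
tables for candidate windows, quantifies their agreement with DVR both
pooled across subject-by-ROI observations and within subject, and
selects the window whose within-subject shared variance with DVR is
highest, tested by repeated-measures ANOVA with Tukey-corrected pairwise
contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .stats import repeated_measures_anova

__all__ = [
    "WindowComparison",
    "compute_suvr",
    "compare_ratio_measures",
    "select_suvr_window",
    "DEFAULT_WINDOWS",
]

DEFAULT_WINDOWS = ((50.0, 70.0), (60.0, 80.0), (70.0, 90.0))


def compute_suvr(target_values, reference_value: float) -> np.ndarray:
    """Elementwise target / reference window means."""
    if not reference_value > 0:
        raise ValueError(f"reference window mean must be positive, got {reference_value}")
    return np.asarray(target_values, float) / float(reference_value)


@dataclass
class WindowComparison:
    """Agreement between one SUVR window and DVR."""

    window: tuple[float, float]
    pooled_r2: float
    pooled_slope: float
    pooled_intercept: float
    per_subject_r2: pd.Series  # indexed by subject_id
    n_pairs: int

    def __post_init__(self) -> None:
        r2s = np.r_[self.pooled_r2, self.per_subject_r2.to_numpy()]
        if np.any((r2s < -1e-12) | (r2s > 1 + 1e-12)):
            raise ValueError("R^2 values must lie in [0, 1]")


def _ratio_long(table: pd.DataFrame, value_col: str) -> pd.DataFrame:
    need = {"subject_id", "region", value_col}
    missing = need - set(table.columns)
    if missing:
        raise ValueError(f"ratio table missing columns {sorted(missing)}")
    return table[["subject_id", "region", value_col]]


def compare_ratio_measures(suvr: pd.DataFrame, dvr: pd.DataFrame,
                           window=(np.nan, np.nan)) -> WindowComparison:
    """Shared variance between SUVR and DVR tables.

    Both tables are long-format with columns ``subject_id, region,
    value``.  Pooled statistics treat every (subject, region) pair as
    one observation in an OLS of SUVR on DVR; the per-subject vector
    holds each subject's own R^2 across their regions.
    """
    merged = pd.merge(_ratio_long(suvr, "value").rename(columns={"value": "suvr"}),
                      _ratio_long(dvr, "value").rename(columns={"value": "dvr"}),
                      on=["subject_id", "region"], how="inner")
    if len(merged) < 3:
        raise ValueError(f"only {len(merged)} shared (subject, region) pairs; need >= 3")
    res = stats.linregress(merged["dvr"], merged["suvr"])
    per = {}
    for sid, sub in merged.groupby("subject_id"):
        if len(sub) < 3:
            raise ValueError(f"subject {sid} has only {len(sub)} shared regions; need >= 3")
        per[sid] = float(stats.linregress(sub["dvr"], sub["suvr"]).rvalue ** 2)
    return WindowComparison(window=tuple(window), pooled_r2=float(res.rvalue ** 2),
                            pooled_slope=float(res.slope),
                            pooled_intercept=float(res.intercept),
                            per_subject_r2=pd.Series(per).sort_index(),
                            n_pairs=len(merged))


@dataclass
class WindowSelection:
    winner: tuple[float, float] | None
    tied: bool
    table: pd.DataFrame           # per-window summary statistics
    anova: dict | None            # repeated-measures ANOVA on per-subject R^2
    contrasts: pd.DataFrame | None  # Tukey pairwise window contrasts


def select_suvr_window(comparisons: list[WindowComparison],
                       alpha: float = 0.05) -> WindowSelection:
    """Pick the acquisition window that best reproduces DVR.

    Primary criterion: highest mean within-subject R^2, tested by a
    repeated-measures ANOVA over the aligned per-subject R^2 vectors
    with Tukey-corrected pairwise contrasts.  Secondary descriptors
    (pooled R^2 and |pooled slope - 1|) are reported, not decisive.
    Exact ties on the primary criterion are flagged with no winner.
    """
    if not comparisons:
        raise ValueError("no window comparisons supplied")
    table = pd.DataFrame({
        "window": [c.window for c in comparisons],
        "mean_within_subject_r2": [float(c.per_subject_r2.mean()) for c in comparisons],
        "pooled_r2": [c.pooled_r2 for c in comparisons],
        "pooled_slope": [c.pooled_slope for c in comparisons],
        "abs_slope_minus_1": [abs(c.pooled_slope - 1.0) for c in comparisons],
    })
    if len(comparisons) == 1:
        return WindowSelection(winner=comparisons[0].window, tied=False,
                               table=table, anova=None, contrasts=None)

    subj_index = comparisons[0].per_subject_r2.index
    for c in comparisons[1:]:
        if not c.per_subject_r2.index.equals(subj_index):
            raise ValueError("per-subject R^2 vectors are not aligned across windows")
    mat = np.column_stack([c.per_subject_r2.to_numpy() for c in comparisons])
    labels = [f"{w[0]:g}-{w[1]:g}" for w in (c.window for c in comparisons)]
    rm = repeated_measures_anova(mat, condition_names=labels)

    best = table["mean_within_subject_r2"].max()
    top = table.index[table["mean_within_subject_r2"] == best].tolist()
    if len(top) > 1:
        return WindowSelection(winner=None, tied=True, table=table,
                               anova=rm["anova"], contrasts=rm["contrasts"])
    return WindowSelection(winner=comparisons[top[0]].window, tied=False,
                           table=table, anova=rm["anova"], contrasts=rm["contrasts"])
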