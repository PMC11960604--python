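"""Reference-region sensitivity analysis and ranking.

A usable reference region for reference-tissue modeling should show
stable late-window uptake across subjects, a reproducible clearance
rate k2', and small residuals when the constrained model (SRTM2) is
forced to explain cortical curves through it.  This module computes
those per-region stability metrics over a cohort and ranks candidate
regions by four criteria — mean SSE, and the coefficients of variation
of SSE, k2' and SUV — all "lower is better".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .frames import TimeActivityCurve, window_average
from .kinetics import ReferenceBasis, derive_k2p, mean_sse, srtm2_fit, srtm_fit

__all__ = [
    "RefRegionMetrics",
    "coefficient_of_variation",
    "evaluate_reference_region",
    "rank_reference_regions",
    "group_invariance_checks",
    "eroded_wm_mask",
]

SUV_WINDOW = (70.0, 90.0)


def coefficient_of_variation(values) -> float:
    """Population coefficient of variation: SD (divisor N) over mean."""
    v = np.asarray(values, float)
    if v.size == 0:
        raise ValueError("coefficient_of_variation of an empty vector")
    m = v.mean()
    if m == 0:
        raise ValueError("coefficient_of_variation undefined for zero mean")
    return float(v.std(ddof=0) / m)


@dataclass
class RefRegionMetrics:
    """Per-subject stability metrics for one candidate reference region."""

    region_name: str
    subject_ids: list
    groups: list
    suv: np.ndarray          # late-window uptake per subject
    k2p: np.ndarray          # pooled reference clearance per subject
    sse: np.ndarray          # mean SRTM2 SSE over cortical ROIs per subject
    suv_cov: float = field(init=False)
    k2p_cov: float = field(init=False)
    sse_cov: float = field(init=False)
    mean_sse: float = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        if not (len(self.suv) == len(self.k2p) == len(self.sse) == n):
            raise ValueError("per-subject vectors must align to one subject index")
        self.suv_cov = coefficient_of_variation(self.suv)
        self.k2p_cov = coefficient_of_variation(self.k2p)
        self.sse_cov = coefficient_of_variation(self.sse)
        self.mean_sse = float(np.mean(self.sse))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"subject_id": self.subject_ids, "group": self.groups,
                             "region": self.region_name, "suv": self.suv,
                             "k2p": self.k2p, "mean_sse": self.sse})


def evaluate_reference_region(region_name: str,
                              reference_tacs: dict[str, TimeActivityCurve],
                              cortical_tacs: dict[str, dict[str, TimeActivityCurve]],
                              groups: dict[str, str] | None = None,
                              suv_window=SUV_WINDOW) -> RefRegionMetrics:
    """Evaluate one candidate reference region over a cohort.

    Parameters
    ----------
    reference_tacs:
        subject_id -> candidate reference TAC.
    cortical_tacs:
        subject_id -> {roi name -> cortical target TAC}.
    groups:
        subject_id -> group label (optional; recorded for downstream
        invariance checks).

    For each subject this computes (i) the late-window SUV of the
    reference curve, (ii) the subject's pooled k2' from per-ROI SRTM
    fits against this reference, and (iii) the mean SSE of SRTM2 re-fits
    at that subject k2'; then the across-subject coefficients of
    variation of all three.
    """
    subject_ids = sorted(cortical_tacs)
    missing = [s for s in subject_ids if s not in reference_tacs]
    if missing:
        raise ValueError(f"subjects missing a reference TAC for {region_name}: {missing}")
    empty = [s for s in subject_ids if not cortical_tacs[s]]
    if empty:
        raise ValueError(f"subjects with no cortical TACs: {empty}")

    suvs, k2ps, sses, grp = [], [], [], []
    for sid in subject_ids:
        ref = reference_tacs[sid]
        basis = ReferenceBasis(ref)
        suvs.append(window_average(ref, suv_window))
        fits = [srtm_fit(tac, ref, basis=basis)
                for tac in cortical_tacs[sid].values()]
        est = derive_k2p(fits)
        k2ps.append(est.k2p)
        refits = [srtm2_fit(tac, ref, est.k2p, basis=basis)
                  for tac in cortical_tacs[sid].values()]
        sses.append(mean_sse(refits))
        grp.append(groups.get(sid, "") if groups else "")
    return RefRegionMetrics(region_name=region_name, subject_ids=subject_ids,
                            groups=grp, suv=np.asarray(suvs),
                            k2p=np.asarray(k2ps), sse=np.asarray(sses))


RANK_CRITERIA = ("mean_sse", "sse_cov", "k2p_cov", "suv_cov")


def rank_reference_regions(metrics: list[RefRegionMetrics]) -> pd.DataFrame:
    """Rank candidate regions; lower is better on every criterion.

    Per-criterion ranks (ties share the mean rank) are averaged into an
    unweighted aggregate rank; the returned table is sorted by it, with
    exact aggregate ties broken by the model-fit criterion (mean SSE).
    """
    if len(metrics) < 2:
        raise ValueError("ranking needs at least 2 candidate regions")
    tbl = pd.DataFrame({
        "region": [m.region_name for m in metrics],
        "mean_sse": [m.mean_sse for m in metrics],
        "sse_cov": [m.sse_cov for m in metrics],
        "k2p_cov": [m.k2p_cov for m in metrics],
        "suv_cov": [m.suv_cov for m in metrics],
        "mean_suv": [float(np.mean(m.suv)) for m in metrics],
        "mean_k2p": [float(np.mean(m.k2p)) for m in metrics],
    })
    for crit in RANK_CRITERIA:
        tbl[f"rank_{crit}"] = stats.rankdata(tbl[crit], method="average")
    tbl["aggregate_rank"] = tbl[[f"rank_{c}" for c in RANK_CRITERIA]].mean(axis=1)
    return tbl.sort_values(["aggregate_rank", "mean_sse", "region"],
                           kind="stable").reset_index(drop=True)


def group_invariance_checks(values, groups, ages, exclude_ids=None,
                            subject_ids=None) -> dict:
    """Test that a reference-region statistic does not track age or group.

    Returns the Pearson correlation of the statistic with age (with an
    optional explicit, logged outlier-exclusion list applied first) and
    a one-way ANOVA across the group labels.  A viable reference region
    should show neither association.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    ages = np.asarray(ages, float)
    if not (len(values) == len(groups) == len(ages)):
        raise ValueError("values, groups and ages must align")
    for g, n in zip(*np.unique(groups, return_counts=True)):
        if n < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")

    keep = np.ones(len(values), bool)
    excluded = []
    if exclude_ids:
        if subject_ids is None:
            raise ValueError("exclude_ids requires subject_ids")
        subject_ids = np.asarray(subject_ids)
        keep = ~np.isin(subject_ids, list(exclude_ids))
        excluded = sorted(set(exclude_ids) & set(subject_ids.tolist()))

    v, a = values[keep], ages[keep]
    degenerate = np.std(v) == 0 or np.std(a) == 0
    if degenerate:
        r, p_r = 0.0, 1.0
    else:
        r, p_r = stats.pearsonr(v, a)

    samples = [values[groups == g] for g in np.unique(groups)]
    if np.std(values) == 0:
        f, p_f = 0.0, 1.0
    else:
        f, p_f = stats.f_oneway(*samples)
        if not np.isfinite(f):
            f, p_f = 0.0, 1.0
    return {"age_r": float(r), "age_p": float(p_r), "age_r_degenerate": bool(degenerate),
            "anova_F": float(f), "anova_p": float(p_f),
            "n_used_for_age": int(keep.sum()), "excluded_ids": excluded}


def eroded_wm_mask(wm_probability: np.ndarray, threshold: float = 0.95,
                   erosion_voxels: int = 1) -> np.ndarray:
    """Eroded white-matter mask: threshold the WM probability map at
    ``threshold`` then apply a one-voxel morphological erosion, keeping
    only deep white matter away from tissue boundaries."""
    mask = np.asarray(wm_probability, float) >= threshold
    if erosion_voxels > 0:
        mask = ndimage.binary_erosion(mask, iterations=erosion_voxels)
    return mask
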