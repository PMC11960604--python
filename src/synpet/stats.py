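"""Cohort statistics: spatial correlations, ANOVA families and the
volume-by-uptake interaction model for cognition.

These are the downstream analyses applied to regional ratio tables:

* within-subject spatial correlation between two modalities across the
  68 bilateral cortical ROIs, with group-level t-tests on the
  per-subject correlations;
* one-way and repeated-measures ANOVA with Tukey-HSD-corrected pairwise
  contrasts;
* the amyloid-burden vs global-uptake association with a
  diagnosis-moderated regression;
* the multiple regression of cognition (MMSE) on regional volume,
  regional uptake, their interaction and age.

All p-values are two-sided; no multiple-testing correction is applied
beyond Tukey where stated.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "spatial_correlation_per_subject",
    "oneway_anova_tukey",
    "repeated_measures_anova",
    "centiloid_association",
    "interaction_regression",
]


def spatial_correlation_per_subject(map_a: pd.DataFrame, map_b: pd.DataFrame,
                                    roi_set, groups: dict | None = None,
                                    fisher_z: bool = False) -> dict:
    """Per-subject Pearson correlation between two regional maps.

    ``map_a`` and ``map_b`` are long tables (``subject_id, region,
    value``); the correlation runs over ``roi_set`` (conventionally the
    68 bilateral cortical ROIs) within each subject.  Returns the
    per-subject r values, a one-sample two-sided t-test of those r
    against 0, and — when exactly two group labels are supplied — a
    two-sample t-test contrasting the groups' r values.

    Group inference runs on raw r by default; set ``fisher_z`` to test
    on variance-stabilized atanh(r) instead (the transform choice is
    recorded in the output).
    """
    roi_set = list(roi_set)
    rs = {}
    for sid in sorted(set(map_a["subject_id"]) & set(map_b["subject_id"])):
        a = map_a[map_a["subject_id"] == sid].set_index("region")["value"]
        b = map_b[map_b["subject_id"] == sid].set_index("region")["value"]
        missing = [r for r in roi_set if r not in a.index or r not in b.index]
        if missing:
            raise ValueError(f"subject {sid} missing ROIs: {missing}")
        rs[sid] = float(stats.pearsonr(a.loc[roi_set], b.loc[roi_set])[0])
    r = pd.Series(rs).sort_index()
    test_vals = np.arctanh(np.clip(r.to_numpy(), -1 + 1e-12, 1 - 1e-12)) \
        if fisher_z else r.to_numpy()
    t, p = stats.ttest_1samp(test_vals, 0.0)
    out = {"per_subject_r": r, "t": float(t), "p": float(p),
           "transform": "fisher_z" if fisher_z else "raw_r"}
    if groups:
        glabels = pd.Series({sid: groups[sid] for sid in r.index})
        uniq = sorted(glabels.unique())
        if len(uniq) == 2:
            va = test_vals[(glabels == uniq[0]).to_numpy()]
            vb = test_vals[(glabels == uniq[1]).to_numpy()]
            t2, p2 = stats.ttest_ind(va, vb)
            out["group_contrast"] = {"groups": uniq, "t": float(t2), "p": float(p2),
                                     "mean_r": {uniq[0]: float(r[glabels == uniq[0]].mean()),
                                                uniq[1]: float(r[glabels == uniq[1]].mean())}}
    return out


def oneway_anova_tukey(values, groups) -> dict:
    """One-way ANOVA with Tukey-HSD pairwise contrasts.

    Degenerate input (zero within- and between-group variance) reports
    F = 0, p = 1 rather than NaN.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2 or np.any(counts < 2):
        raise ValueError("need >= 2 groups with >= 2 members each")
    samples = [values[groups == g] for g in uniq]

    grand = values.mean()
    ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df_b, df_w = len(uniq) - 1, len(values) - len(uniq)
    if ss_within == 0 and ss_between == 0:
        f, p = 0.0, 1.0
        pair_rows = [{"group_a": a, "group_b": b, "diff": 0.0, "p_tukey": 1.0}
                     for a, b in combinations(uniq, 2)]
        return {"F": f, "p": p, "df": (df_b, df_w),
                "contrasts": pd.DataFrame(pair_rows)}
    ms_w = ss_within / df_w
    f = (ss_between / df_b) / ms_w if ms_w > 0 else np.inf
    p = float(stats.f.sf(f, df_b, df_w)) if np.isfinite(f) else 0.0

    pair_rows = []
    for (ia, a), (ib, b) in combinations(enumerate(uniq), 2):
        sa, sb = samples[ia], samples[ib]
        diff = sb.mean() - sa.mean()
        if ms_w > 0:
            se = np.sqrt(ms_w / 2 * (1 / len(sa) + 1 / len(sb)))  # Tukey-Kramer
            q = abs(diff) / se
            p_t = float(stats.studentized_range.sf(q, len(uniq), df_w))
        else:
            p_t = 1.0 if diff == 0 else 0.0
        pair_rows.append({"group_a": a, "group_b": b, "diff": float(diff),
                          "p_tukey": p_t})
    return {"F": float(f), "p": p, "df": (df_b, df_w),
            "contrasts": pd.DataFrame(pair_rows)}


def repeated_measures_anova(values: np.ndarray, condition_names=None) -> dict:
    """One-within-factor repeated-measures ANOVA with Tukey contrasts.

    ``values`` is a complete subjects x conditions matrix (no missing
    cells; nothing is imputed).  Implemented as the subject-blocked
    two-way decomposition without interaction: the condition effect is
    tested against MS_residual with (k-1, (k-1)(n-1)) degrees of
    freedom.  Pairwise condition contrasts use the studentized range
    with the blocked error term.
    """
    m = np.asarray(values, float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a subjects x conditions matrix, both dims >= 2")
    if np.any(~np.isfinite(m)):
        raise ValueError("missing cells are not allowed (no imputation)")
    n, k = m.shape
    names = list(condition_names) if condition_names is not None else \
        [f"c{j}" for j in range(k)]
    grand = m.mean()
    cond_means = m.mean(axis=0)
    subj_means = m.mean(axis=1)
    ss_cond = n * ((cond_means - grand) ** 2).sum()
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_total = ((m - grand) ** 2).sum()
    ss_resid = ss_total - ss_cond - ss_subj
    df_cond, df_resid = k - 1, (k - 1) * (n - 1)
    ms_resid = ss_resid / df_resid
    if ms_resid <= 0:
        f = 0.0 if ss_cond == 0 else np.inf
        p = 1.0 if ss_cond == 0 else 0.0
    else:
        f = (ss_cond / df_cond) / ms_resid
        p = float(stats.f.sf(f, df_cond, df_resid))

    rows = []
    for i, j in combinations(range(k), 2):
        diff = cond_means[j] - cond_means[i]
        if ms_resid > 0:
            q = abs(diff) / np.sqrt(ms_resid / n)
            p_t = float(stats.studentized_range.sf(q, k, df_resid))
        else:
            p_t = 1.0 if diff == 0 else 0.0
        rows.append({"condition_a": names[i], "condition_b": names[j],
                     "diff": float(diff), "p_tukey": p_t})
    return {"anova": {"F": float(f), "p": float(p), "df": (df_cond, df_resid),
                      "ss": {"condition": float(ss_cond), "subject": float(ss_subj),
                             "residual": float(ss_resid), "total": float(ss_total)}},
            "contrasts": pd.DataFrame(rows)}


def centiloid_association(centiloid, global_uptake, diagnosis) -> dict:
    """Amyloid burden versus global tracer uptake in the amyloid-positive
    subset: Pearson correlation plus an OLS of centiloid on uptake,
    diagnosis and their interaction with coefficient t-tests."""
    c = np.asarray(centiloid, float)
    u = np.asarray(global_uptake, float)
    d = pd.Series(diagnosis)
    if len(c) < 4:
        raise ValueError("need n >= 4 amyloid-positive subjects")
    if np.std(u) == 0 or np.std(c) == 0 or d.nunique() < 2:
        raise ValueError("constant predictor or outcome in centiloid association")
    r, p_r = stats.pearsonr(u, c)
    d_num = pd.get_dummies(d, drop_first=True).iloc[:, 0].to_numpy(float)
    X = sm.add_constant(np.column_stack([u, d_num, u * d_num]))
    fit = sm.OLS(c, X).fit()
    names = ["intercept", "uptake", "diagnosis", "uptake_x_diagnosis"]
    coef = pd.DataFrame({"term": names, "estimate": fit.params,
                         "t": fit.tvalues, "p": fit.pvalues})
    return {"r": float(r), "p": float(p_r), "coefficients": coef,
            "adj_r2": float(fit.rsquared_adj), "model_p": float(fit.f_pvalue),
            "n": len(c)}


def interaction_regression(mmse, volume_norm, uptake, age,
                           grid_points: int = 25) -> dict:
    """MMSE ~ volume + uptake + volume x uptake + age, complete cases.

    ``volume_norm`` is the composite-ROI gray-matter volume already
    normalized by total intracranial volume.  Besides the coefficient
    table and adjusted R^2, returns a prediction grid evaluating MMSE
    over the observed volume range at the minimum, mean and maximum
    observed uptake (age held at its mean) — the surface showing whether
    high uptake buffers the cognitive cost of low volume.
    """
    y = np.asarray(mmse, float)
    v = np.asarray(volume_norm, float)
    u = np.asarray(uptake, float)
    a = np.asarray(age, float)
    if not (len(y) == len(v) == len(u) == len(a)):
        raise ValueError("inputs must align")
    X = np.column_stack([v, u, v * u, a])
    Xc = sm.add_constant(X)
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear predictors)")
    fit = sm.OLS(y, Xc).fit()
    names = ["intercept", "volume", "uptake", "volume_x_uptake", "age"]
    coef = pd.DataFrame({"term": names, "estimate": fit.params,
                         "t": fit.tvalues, "p": fit.pvalues})

    v_grid = np.linspace(v.min(), v.max(), grid_points)
    grid_rows = []
    for label, u_level in (("min", u.min()), ("mean", u.mean()), ("max", u.max())):
        Xg = sm.add_constant(
            np.column_stack([v_grid, np.full_like(v_grid, u_level),
                             v_grid * u_level, np.full_like(v_grid, a.mean())]),
            has_constant="add")
        pred = fit.predict(Xg)
        grid_rows.append(pd.DataFrame({"uptake_level": label, "uptake": u_level,
                                       "volume": v_grid, "predicted_mmse": pred}))
    return {"coefficients": coef, "adj_r2": float(fit.rsquared_adj),
            "model_p": float(fit.f_pvalue), "n": len(y),
            "prediction_grid": pd.concat(grid_rows, ignore_index=True),
            "fitted_values": np.asarray(fit.fittedvalues)}
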