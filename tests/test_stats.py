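"""ANOVA families, spatial correlations and the interaction regression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from synpet.stats import (centiloid_association, interaction_regression,
                          oneway_anova_tukey, repeated_measures_anova,
                          spatial_correlation_per_subject)


def _maps(values_by_subject):
    rows = [{"subject_id": sid, "region": f"r{j}", "value": v}
            for sid, vals in values_by_subject.items() for j, v in enumerate(vals)]
    return pd.DataFrame(rows)


class TestSpatialCorrelation:
    def test_anticorrelated_maps(self):
        rng = np.random.default_rng(0)
        a = {f"s{i}": rng.uniform(1, 2, 20) for i in range(6)}
        b = {sid: -v for sid, v in a.items()}
        out = spatial_correlation_per_subject(_maps(a), _maps(b),
                                              [f"r{j}" for j in range(20)])
        assert np.allclose(out["per_subject_r"], -1.0)
        assert out["t"] < -10

    def test_identical_maps(self):
        rng = np.random.default_rng(1)
        a = {f"s{i}": rng.uniform(1, 2, 10) for i in range(4)}
        out = spatial_correlation_per_subject(_maps(a), _maps(a),
                                              [f"r{j}" for j in range(10)])
        assert np.allclose(out["per_subject_r"], 1.0)

    def test_missing_roi_listed(self):
        a = _maps({"s0": [1.0, 2.0]})
        with pytest.raises(ValueError, match="r9"):
            spatial_correlation_per_subject(a, a, ["r0", "r9"])

    def test_patient_anticorrelation_detected_in_most_reps(self):
        # generative oracle: rho = -0.5 in patients, 0 in controls,
        # built directly from the bivariate construction
        n_roi, hits, n_rep = 68, 0, 100
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            maps_a, maps_b, groups = {}, {}, {}
            for i in range(21):
                grp = "patient" if i < 7 else "O"
                rho = -0.5 if grp == "patient" else 0.0
                z = rng.normal(size=n_roi)
                e = rng.normal(size=n_roi)
                maps_a[f"s{i:02d}"] = 1.5 + 0.3 * z
                maps_b[f"s{i:02d}"] = 1.2 + 0.1 * (rho * z + np.sqrt(1 - rho**2) * e)
                groups[f"s{i:02d}"] = grp
            out = spatial_correlation_per_subject(
                _maps(maps_a), _maps(maps_b), [f"r{j}" for j in range(n_roi)],
                groups=groups)
            gc = out["group_contrast"]
            patient_lower = gc["mean_r"]["patient"] < gc["mean_r"]["O"]
            hits += patient_lower and gc["p"] < 0.05
        assert hits / n_rep >= 0.90


class TestOnewayAnova:
    def test_identical_group_patterns(self):
        vals = [1, 2, 3] * 3
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        out = oneway_anova_tukey(vals, groups)
        assert out["F"] == pytest.approx(0.0)
        assert (out["contrasts"]["p_tukey"] == 1.0).all()

    def test_degenerate_all_equal(self):
        out = oneway_anova_tukey([2.0] * 6, ["a", "a", "b", "b", "c", "c"])
        assert out["F"] == 0.0 and out["p"] == 1.0

    def test_matches_hand_computation(self):
        vals = np.array([1.0, 2, 3, 6, 7, 9])
        groups = np.array(["a", "a", "a", "b", "b", "b"])
        out = oneway_anova_tukey(vals, groups)
        grand = vals.mean()
        ssb = 3 * ((2 - grand) ** 2 + (22 / 3 - grand) ** 2)
        ssw = sum((vals[:3] - 2) ** 2) + sum((vals[3:] - 22 / 3) ** 2)
        assert out["F"] == pytest.approx((ssb / 1) / (ssw / 4))
        assert out["df"] == (1, 4)

    def test_matches_scipy_tukey_hsd(self):
        rng = np.random.default_rng(5)
        samples = [rng.normal(m, 1, 8) for m in (0, 0.5, 2)]
        vals = np.concatenate(samples)
        groups = np.repeat(["a", "b", "c"], 8)
        out = oneway_anova_tukey(vals, groups)
        ref = sps.tukey_hsd(*samples)
        mine = out["contrasts"].set_index(["group_a", "group_b"])["p_tukey"]
        for (i, a), (j, b) in [((0, "a"), (1, "b")), ((0, "a"), (2, "c")),
                               ((1, "b"), (2, "c"))]:
            assert mine.loc[(a, b)] == pytest.approx(ref.pvalue[i, j], abs=1e-6)

    def test_ss_decomposition_identity(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=30)
        groups = np.repeat(["a", "b", "c"], 10)
        ss_total = ((vals - vals.mean()) ** 2).sum()
        ssb = sum(10 * (vals[groups == g].mean() - vals.mean()) ** 2 for g in "abc")
        ssw = sum(((vals[groups == g] - vals[groups == g].mean()) ** 2).sum()
                  for g in "abc")
        assert ssb + ssw == pytest.approx(ss_total, abs=1e-10)

    def test_tukey_p_monotone_in_mean_difference(self):
        rng = np.random.default_rng(7)
        base = rng.normal(0, 1, 10)
        ps = []
        for delta in (0.5, 1.5, 3.0):
            vals = np.concatenate([base, base + delta])
            out = oneway_anova_tukey(vals, np.repeat(["a", "b"], 10))
            ps.append(out["contrasts"]["p_tukey"].iloc[0])
        assert ps[0] > ps[1] > ps[2]


class TestRepeatedMeasures:
    def test_identical_conditions(self):
        m = np.tile(np.arange(5.0)[:, None], (1, 3))
        out = repeated_measures_anova(m)
        assert out["anova"]["F"] == 0.0

    def test_pure_condition_effect_df_and_p(self):
        n, k = 8, 3
        m = np.tile(np.array([0.0, 1.0, 2.0]), (n, 1)) \
            + np.arange(n)[:, None]  # subject offsets, zero residual
        out = repeated_measures_anova(m)
        assert out["anova"]["df"] == (k - 1, (k - 1) * (n - 1))
        assert out["anova"]["p"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        n, k = 12, 3
        m = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
        out = repeated_measures_anova(m)
        df = pd.DataFrame({"y": m.ravel(),
                           "cond": np.tile(np.arange(k), n),
                           "subj": np.repeat(np.arange(n), k)})
        ref = pg.rm_anova(data=df, dv="y", within="cond", subject="subj")
        p_col = "p_unc" if "p_unc" in ref.columns else "p-unc"
        assert out["anova"]["F"] == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert out["anova"]["p"] == pytest.approx(float(ref[p_col].iloc[0]), rel=1e-6)

    def test_missing_cells_rejected(self):
        m = np.ones((4, 3))
        m[1, 2] = np.nan
        with pytest.raises(ValueError, match="missing"):
            repeated_measures_anova(m)

    def test_ss_identity(self):
        rng = np.random.default_rng(9)
        m = rng.normal(size=(10, 4))
        ss = repeated_measures_anova(m)["anova"]["ss"]
        assert ss["condition"] + ss["subject"] + ss["residual"] == pytest.approx(
            ss["total"], abs=1e-10)


class TestCentiloid:
    def test_noiseless_negative_relation(self):
        rng = np.random.default_rng(10)
        u = rng.uniform(1, 2, 12)
        c = 100 - 40 * u
        d = ["O"] * 6 + ["patient"] * 6
        out = centiloid_association(c, u, d)
        assert out["r"] == pytest.approx(-1.0)
        coef = out["coefficients"].set_index("term")
        assert coef.loc["uptake_x_diagnosis", "estimate"] == pytest.approx(0.0, abs=1e-9)

    def test_permuted_uptake_rarely_significant(self):
        hits, n_rep = 0, 100
        for rep in range(n_rep):
            rng = np.random.default_rng(2000 + rep)
            u = rng.uniform(1, 2, 12)
            c = rng.normal(50, 20, 12)
            out = centiloid_association(c, u, ["O"] * 6 + ["patient"] * 6)
            hits += out["p"] < 0.05
        assert hits / n_rep <= 0.10

    def test_generative_slope_in_ci_most_reps(self):
        hits, n_rep = 0, 100
        for rep in range(n_rep):
            rng = np.random.default_rng(3000 + rep)
            u = rng.uniform(1, 2, 12)
            c = 170 - 75 * u + rng.normal(0, 8, 12)
            slope, intercept, *_ = sps.linregress(u, c)
            res = sps.linregress(u, c)
            ci = sps.t.ppf(0.975, 10) * res.stderr
            hits += abs(res.slope - (-75)) <= ci
        assert hits / n_rep >= 0.90

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            centiloid_association(np.ones(6) * 50, np.ones(6),
                                  ["O"] * 3 + ["patient"] * 3)


class TestInteractionRegression:
    def _data(self, bint, noise_sd, seed=0, n=24):
        rng = np.random.default_rng(seed)
        v = rng.uniform(0.014, 0.024, n)
        u = rng.uniform(1.2, 2.2, n)
        a = rng.uniform(20, 85, n)
        y = 20 + 300 * v + 2 * u + bint * v * u - 0.02 * a \
            + rng.normal(0, noise_sd, n)
        return y, v, u, a

    def test_zero_interaction_noiseless(self):
        y, v, u, a = self._data(bint=0.0, noise_sd=0.0)
        out = interaction_regression(y, v, u, a)
        coef = out["coefficients"].set_index("term")
        assert coef.loc["volume_x_uptake", "estimate"] == pytest.approx(0.0, abs=1e-6)
        assert out["adj_r2"] == pytest.approx(1.0)

    def test_negative_interaction_detected_and_grid_shape(self):
        y, v, u, a = self._data(bint=-400.0, noise_sd=0.2, seed=4)
        out = interaction_regression(y, v, u, a)
        coef = out["coefficients"].set_index("term")
        assert coef.loc["volume_x_uptake", "t"] < 0
        grid = out["prediction_grid"]
        # at max uptake the predicted MMSE drop across the volume range
        # is smallest (high uptake buffers low volume)
        drops = {}
        for lvl, sub in grid.groupby("uptake_level"):
            sub = sub.sort_values("volume")
            drops[lvl] = sub["predicted_mmse"].iloc[-1] - sub["predicted_mmse"].iloc[0]
        assert drops["max"] < drops["min"]

    def test_centering_invariance(self):
        y, v, u, a = self._data(bint=-400.0, noise_sd=0.3, seed=5)
        out1 = interaction_regression(y, v, u, a)
        out2 = interaction_regression(y, v - v.mean(), u - u.mean(), a)
        c1 = out1["coefficients"].set_index("term")["estimate"]
        c2 = out2["coefficients"].set_index("term")["estimate"]
        assert c2["volume_x_uptake"] == pytest.approx(c1["volume_x_uptake"], rel=1e-10)
        np.testing.assert_allclose(out1["fitted_values"], out2["fitted_values"],
                                   atol=1e-10)

    def test_residual_orthogonality(self):
        y, v, u, a = self._data(bint=-100.0, noise_sd=1.0, seed=6)
        out = interaction_regression(y, v, u, a)
        resid = y - out["fitted_values"]
        for col in (np.ones_like(v), v, u, v * u, a):
            assert abs(np.dot(resid, col)) < 1e-7 * np.linalg.norm(col) * len(y)

    def test_collinear_design_rejected(self):
        y, v, u, a = self._data(bint=0.0, noise_sd=0.1, seed=7)
        with pytest.raises(ValueError, match="rank"):
            interaction_regression(y, v, u, v)  # age duplicates volume


def test_pearson_bounds_and_sign_flip():
    rng = np.random.default_rng(11)
    x = rng.normal(size=50)
    r, _ = sps.pearsonr(x, -x)
    assert r == pytest.approx(-1.0)
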