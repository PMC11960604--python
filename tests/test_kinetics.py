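"""SRTM/SRTM2 fitting, k2' pooling and reference Logan analysis."""

import numpy as np
import pytest

from conftest import REF_K2, srtm_forward
from synpet.frames import TimeActivityCurve
from synpet.kinetics import (KineticFit, ReferenceBasis, cohort_steady_state_test,
                             derive_k2p, logan_ref, logan_steady_state_check,
                             mean_sse, srtm2_fit, srtm_fit, voxelwise_ratio_image)
from synpet.simulate import add_tac_noise, simulate_tissue_tac

DV_REF = 0.3 / 0.055  # distribution volume of the reference tissue


def one_tc_target(dvr, k2, plasma, schedule):
    """1TC target with a prescribed ground-truth DVR."""
    return simulate_tissue_tac(dvr * DV_REF * k2, k2, plasma, schedule)


class TestSrtm:
    def test_identity_target(self, ref_tac):
        fit = srtm_fit(ref_tac, ref_tac)
        assert fit.r1 == pytest.approx(1.0, abs=1e-6)
        assert fit.bp_nd == pytest.approx(0.0, abs=1e-3)

    def test_noiseless_forward_recovery(self, ref_basis):
        target = srtm_forward(ref_basis, r1=0.9, k2p=0.055, bp_nd=1.5)
        fit = srtm_fit(target, ref_basis.reference, basis=ref_basis)
        assert fit.r1 == pytest.approx(0.9, rel=0.01)
        assert fit.bp_nd == pytest.approx(1.5, rel=0.01)
        assert fit.k2p == pytest.approx(0.055, rel=0.01)

    def test_noisy_replicates_median_bp(self, ref_basis, schedule):
        target = srtm_forward(ref_basis, r1=0.9, k2p=0.055, bp_nd=1.5)
        bps = []
        for rep in range(200):
            noisy = add_tac_noise(target, schedule, sigma0=0.15, seed=(555, rep))
            bps.append(srtm_fit(noisy, ref_basis.reference, basis=ref_basis).bp_nd)
        assert np.median(bps) == pytest.approx(1.5, rel=0.05)

    def test_zero_reference_rejected(self, schedule):
        zero = TimeActivityCurve.from_schedule(schedule, np.zeros(35))
        tac = TimeActivityCurve.from_schedule(schedule, np.ones(35))
        with pytest.raises(ValueError, match="zero"):
            srtm_fit(tac, zero)


class TestSrtm2:
    def test_identity_with_true_clearance(self, ref_tac):
        fit = srtm2_fit(ref_tac, ref_tac, k2p=REF_K2)
        assert fit.r1 == pytest.approx(1.0, abs=1e-4)
        assert fit.bp_nd == pytest.approx(0.0, abs=1e-3)

    def test_noiseless_recovery_at_true_k2p(self, ref_basis):
        target = srtm_forward(ref_basis, r1=0.9, k2p=0.055, bp_nd=1.5)
        fit = srtm2_fit(target, ref_basis.reference, k2p=0.055, basis=ref_basis)
        assert fit.r1 == pytest.approx(0.9, rel=0.01)
        assert fit.bp_nd == pytest.approx(1.5, rel=0.01)

    def test_misspecified_k2p_increases_sse(self, ref_basis):
        # profile-SSE sanity: the generating k2' fits strictly better
        target = srtm_forward(ref_basis, r1=0.9, k2p=0.055, bp_nd=1.5)
        sse_true = srtm2_fit(target, ref_basis.reference, 0.055, basis=ref_basis).sse
        sse_off = srtm2_fit(target, ref_basis.reference, 0.055 * 1.5,
                            basis=ref_basis).sse
        assert sse_off > sse_true

    def test_invalid_k2p(self, ref_tac):
        with pytest.raises(ValueError):
            srtm2_fit(ref_tac, ref_tac, k2p=0.0)


class TestDeriveK2p:
    def _fit(self, k2p, boundary=False, bp=1.0):
        return KineticFit(r1=1.0, k2=k2p, k2a=k2p / (bp + 1), bp_nd=bp, k2p=k2p,
                          sse=0.0, fitted_values=np.zeros(1), at_boundary=boundary)

    def test_shared_clearance(self):
        est = derive_k2p([self._fit(0.06)] * 5)
        assert est.k2p == pytest.approx(0.06)
        assert est.n_excluded == 0

    def test_boundary_and_low_bp_excluded(self):
        fits = [self._fit(0.06), self._fit(0.2, boundary=True), self._fit(0.2, bp=-0.9)]
        est = derive_k2p(fits)
        assert est.k2p == pytest.approx(0.06)
        assert est.n_excluded == 2

    def test_all_filtered_raises(self):
        with pytest.raises(ValueError, match="excluded"):
            derive_k2p([self._fit(0.06, boundary=True)])

    def test_noiseless_multi_roi_subject(self, ref_basis):
        rng = np.random.default_rng(2)
        fits = []
        for _ in range(34):
            target = srtm_forward(ref_basis, r1=rng.uniform(0.8, 1.1), k2p=0.055,
                                  bp_nd=rng.uniform(0.5, 1.5))
            fits.append(srtm_fit(target, ref_basis.reference, basis=ref_basis))
        assert derive_k2p(fits).k2p == pytest.approx(0.055, rel=0.01)

    def test_cohort_group_average_recovery_at_cohort_noise(self, cohort28):
        # group-mean estimated k2' tracks the generating per-subject truths
        ratios = []
        for s in cohort28.subjects:
            ref = s.reference_tacs["cereb_gm"]
            basis = ReferenceBasis(ref)
            fits = [srtm_fit(t, ref, basis=basis) for t in s.cortical_tacs.values()]
            ratios.append(derive_k2p(fits).k2p / s.k2p)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.03)


class TestMeanSse:
    def test_examples(self):
        f = lambda s: KineticFit(1, 0.05, 0.02, 1.5, 0.05, s, np.zeros(1))
        assert mean_sse([f(0.0), f(0.0)]) == 0.0
        assert mean_sse([f(1.0), f(3.0)]) == 2.0

    def test_matches_residual_recomputation(self, ref_basis, schedule):
        target = srtm_forward(ref_basis, r1=0.95, k2p=0.055, bp_nd=1.2)
        noisy = add_tac_noise(target, schedule, 0.1, seed=3)
        fit = srtm_fit(noisy, ref_basis.reference, basis=ref_basis)
        w = schedule.duration_weights()
        sse = np.sum(w * (noisy.values - fit.fitted_values) ** 2)
        assert fit.sse == pytest.approx(sse, rel=1e-8)
        assert mean_sse([fit]) == pytest.approx(sse, rel=1e-8)


class TestLogan:
    def test_identity_dvr_one(self, ref_tac):
        fit = logan_ref(ref_tac, ref_tac, k2p=REF_K2, t_star=35, t_end=90)
        assert fit.dvr == pytest.approx(1.0, rel=0.01)

    def test_noiseless_1tc_dvr2(self, ref_tac, plasma, schedule):
        target = one_tc_target(2.0, 0.04, plasma, schedule)
        fit = logan_ref(target, ref_tac, k2p=REF_K2, t_star=35, t_end=90)
        assert fit.dvr == pytest.approx(2.0, rel=0.03)

    def test_dvr_sweep_monotone(self, ref_tac, plasma, schedule):
        est = []
        for dvr in (0.5, 1.0, 1.5, 2.5):
            target = one_tc_target(dvr, 0.04, plasma, schedule)
            fit = logan_ref(target, ref_tac, k2p=REF_K2, t_star=35, t_end=90)
            assert fit.dvr == pytest.approx(dvr, rel=0.03)
            est.append(fit.dvr)
        assert np.all(np.diff(est) > 0)

    def test_rescaling_invariance(self, ref_tac, plasma, schedule):
        target = one_tc_target(1.8, 0.05, plasma, schedule)
        f1 = logan_ref(target, ref_tac, REF_K2)
        f2 = logan_ref(target.scaled(7.3), ref_tac.scaled(7.3), REF_K2)
        assert f2.dvr == pytest.approx(f1.dvr, rel=1e-12)

    def test_consistency_with_srtm2_bp(self, ref_basis):
        target = srtm_forward(ref_basis, r1=0.95, k2p=0.055, bp_nd=1.0)
        logan = logan_ref(target, ref_basis.reference, k2p=0.055)
        srtm2 = srtm2_fit(target, ref_basis.reference, 0.055, basis=ref_basis)
        assert logan.dvr == pytest.approx(srtm2.bp_nd + 1.0, rel=0.05)

    def test_too_few_frames_rejected(self, ref_tac):
        with pytest.raises(ValueError, match=">= 3"):
            logan_ref(ref_tac, ref_tac, REF_K2, t_star=80, t_end=90)

    def test_nonpositive_target_rejected(self, ref_tac, schedule):
        bad = TimeActivityCurve.from_schedule(schedule, np.r_[np.ones(34), 0.0])
        with pytest.raises(ValueError, match="positive"):
            logan_ref(bad, ref_tac, REF_K2)

    def test_bias_small_and_rmse_shrinks_with_noise(self, ref_tac, plasma, schedule):
        target = one_tc_target(2.0, 0.04, plasma, schedule)
        rmse = {}
        for sigma0 in (0.2, 0.1):
            est = []
            for rep in range(200):
                noisy = add_tac_noise(target, schedule, sigma0, seed=(77, rep))
                est.append(logan_ref(noisy, ref_tac, REF_K2).dvr)
            est = np.array(est)
            if sigma0 == 0.1:
                assert abs(est.mean() - 2.0) / 2.0 < 0.02  # bias
            rmse[sigma0] = np.sqrt(np.mean((est - 2.0) ** 2))
        assert rmse[0.1] < rmse[0.2]


class TestSteadyState:
    def test_exactly_linear_plot(self, ref_tac, plasma, schedule):
        target = one_tc_target(1.5, 0.2, plasma, schedule)  # fast equilibration
        fit = logan_ref(target, ref_tac, REF_K2, 35, 90)
        chk = logan_steady_state_check(fit)
        assert abs(chk.difference) < 0.005

    def test_slow_kinetics_reproducible_sign(self, ref_tac, plasma, schedule):
        target = simulate_tissue_tac(0.3, 0.01, plasma, schedule)  # k2a = 0.01/min
        signs = set()
        for rep in range(3):
            fit = logan_ref(target, ref_tac, REF_K2, 35, 90)
            chk = logan_steady_state_check(fit)
            signs.add(np.sign(chk.difference))
        assert len(signs) == 1 and 0 not in signs

    def test_cohort_paired_t(self, ref_tac, plasma, schedule):
        checks = []
        for k2 in (0.15, 0.18, 0.2):
            fit = logan_ref(one_tc_target(1.5, k2, plasma, schedule), ref_tac,
                            REF_K2, 35, 90)
            checks.append(logan_steady_state_check(fit))
        out = cohort_steady_state_test(checks)
        assert out["n"] == 3
        assert np.isfinite(out["t"])


class TestVoxelwise:
    def test_homogeneous_regions_match_roi_level(self, ref_tac, plasma, schedule):
        from synpet.simulate import generate_phantom
        t1 = one_tc_target(1.5, 0.04, plasma, schedule)
        t2 = one_tc_target(2.2, 0.06, plasma, schedule)
        shapes = [
            {"label": 1, "kind": "box", "center": (4, 4, 4), "size": (2, 2, 2),
             "value": t1.values},
            {"label": 2, "kind": "box", "center": (11, 11, 11), "size": (2, 2, 2),
             "value": t2.values},
        ]
        img, labels, _ = generate_phantom(shapes, grid_shape=(16, 16, 16),
                                          schedule=schedule)
        mask = labels > 0
        out = voxelwise_ratio_image(img, ref_tac, "logan", mask, k2p=REF_K2)
        roi1 = logan_ref(t1, ref_tac, REF_K2).dvr
        roi2 = logan_ref(t2, ref_tac, REF_K2).dvr
        assert np.allclose(out[labels == 1], roi1, rtol=1e-9)
        assert np.allclose(out[labels == 2], roi2, rtol=1e-9)
        assert np.all(np.isnan(out[~mask]))

    def test_noisy_phantom_median_near_roi_value(self, ref_tac, plasma, schedule):
        from synpet.simulate import generate_phantom
        t1 = one_tc_target(2.0, 0.04, plasma, schedule)
        shapes = [{"label": 1, "kind": "box", "center": (5, 5, 5), "size": (3, 3, 3),
                   "value": t1.values}]
        img, labels, _ = generate_phantom(shapes, grid_shape=(12, 12, 12),
                                          schedule=schedule, sigma0=0.3, seed=5)
        out = voxelwise_ratio_image(img, ref_tac, "logan", labels > 0, k2p=REF_K2)
        roi = logan_ref(t1, ref_tac, REF_K2).dvr
        assert np.nanmedian(out[labels == 1]) == pytest.approx(roi, rel=0.05)

    def test_suvr_method(self, ref_tac, plasma, schedule):
        from synpet.simulate import generate_phantom
        t1 = one_tc_target(1.5, 0.05, plasma, schedule)
        shapes = [{"label": 1, "kind": "box", "center": (4, 4, 4), "size": (2, 2, 2),
                   "value": t1.values}]
        img, labels, _ = generate_phantom(shapes, grid_shape=(9, 9, 9),
                                          schedule=schedule)
        out = voxelwise_ratio_image(img, ref_tac, "suvr", labels > 0,
                                    window=(60, 80))
        from synpet.frames import window_average
        expected = window_average(t1, (60, 80)) / window_average(ref_tac, (60, 80))
        assert np.allclose(out[labels == 1], expected, rtol=1e-9)
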