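"""Normalization chain: median-of-ratios identities, hand fixtures, QC bands."""

import numpy as np
import pandas as pd
import pytest

from somastrat.normalize import (
    NormFactors,
    build_global_reference,
    calibrate,
    hybridization_normalize,
    intraplate_median_normalize,
    median_normalize_to_reference,
    normalize_pipeline,
    plate_scale,
    qc_report,
)
from somastrat.simulate import SimConfig, simulate_cohort

from conftest import make_table


def _plate_with_controls(rng, n_samples=8, n_analytes=20, n_hyb=12):
    """One plate: study samples + 3 calibrators, hyb controls appended."""
    n = n_samples + 3
    base = rng.lognormal(7, 1, size=n_analytes)
    bias = rng.uniform(0.7, 1.4, size=n)
    rfu = np.empty((n, n_analytes + n_hyb))
    rfu[:, :n_analytes] = base[None, :] * bias[:, None] * rng.lognormal(0, 0.05, (n, n_analytes))
    hyb_levels = np.geomspace(50, 30000, n_hyb)
    rfu[:, n_analytes:] = hyb_levels[None, :] * bias[:, None] * rng.lognormal(0, 0.02, (n, n_hyb))
    dil = [1 + j % 3 for j in range(n_analytes)] + [1] * n_hyb
    hyb = [False] * n_analytes + [True] * n_hyb
    stype = ["study"] * n_samples + ["calibrator"] * 3
    return make_table(rfu, dilution=dil, hyb=hyb, sample_type=stype)


class TestHybridization:
    def test_sample_at_plate_medians_unchanged(self):
        # 3 samples; middle sample holds the median of every control
        rfu = np.array([[10.0, 100.0, 4.0],
                        [20.0, 200.0, 8.0],
                        [40.0, 400.0, 16.0]])
        t = make_table(rfu, hyb=[True, True, False])
        out, f = hybridization_normalize(t)
        assert f.hyb["S1"] == pytest.approx(1.0)
        assert np.allclose(out.rfu.loc["S1"], rfu[1])

    def test_low_controls_scale_sample_up(self):
        rfu = np.array([[30.0, 300.0, 7.0],
                        [20.0, 200.0, 8.0],
                        [40.0, 400.0, 16.0],
                        [10.0, 100.0, 5.0]])
        t = make_table(rfu, hyb=[True, True, False])
        out, f = hybridization_normalize(t)
        # plate medians: control0 -> 25, control1 -> 250; S3 ratios (2.5, 2.5)
        assert f.hyb["S3"] == pytest.approx(2.5)
        assert np.allclose(out.rfu.loc["S3"], rfu[3] * 2.5)

    def test_post_hoc_median_control_ratio_is_one(self):
        rng = np.random.default_rng(0)
        t = _plate_with_controls(rng)
        hyb = t.hyb_control_ids()
        ref = t.rfu[hyb].median(axis=0)  # defining (pre-scaling) reference
        out, _ = hybridization_normalize(t)
        for s in out.rfu.index:
            ratios = ref / out.rfu.loc[s, hyb]
            assert np.median(ratios) == pytest.approx(1.0, abs=1e-12)

    def test_zero_control_rfu_errors(self):
        rfu = np.array([[0.0, 5.0], [1.0, 6.0]])
        t = make_table(rfu, hyb=[True, False])
        with pytest.raises(ValueError):
            hybridization_normalize(t)

    def test_missing_controls_errors(self):
        t = make_table([[1.0, 2.0]], hyb=[False, False])
        with pytest.raises(ValueError, match="hybridization"):
            hybridization_normalize(t)


class TestIntraplate:
    def test_calibrator_at_plate_medians_has_unit_factors(self):
        rng = np.random.default_rng(1)
        t = _plate_with_controls(rng)
        # force all calibrators identical -> every factor exactly 1
        cal = t.samples_of_type("calibrator")
        t.rfu.loc[cal] = t.rfu.loc[cal].iloc[0].to_numpy()[None, :]
        out, f = intraplate_median_normalize(t)
        assert np.allclose(f.intraplate["factor"], 1.0)

    def test_three_calibrator_hand_fixture(self):
        # every analyte: calibrators at 2, 4, 8 -> local median 4,
        # factors = 4/2, 4/4, 4/8 = (2, 1, 0.5)
        n_an = 5
        rfu = np.array([[2.0] * n_an, [4.0] * n_an, [8.0] * n_an])
        t = make_table(rfu, sample_type=["calibrator"] * 3)
        out, f = intraplate_median_normalize(t)
        fac = f.intraplate.set_index("sample_id")["factor"]
        assert fac["S0"] == pytest.approx(2.0)
        assert fac["S1"] == pytest.approx(1.0)
        assert fac["S2"] == pytest.approx(0.5)
        assert np.allclose(out.rfu.to_numpy(), 4.0)

    def test_post_hoc_per_dilution_median_ratio_is_one(self):
        rng = np.random.default_rng(2)
        t = _plate_with_controls(rng)
        cal = t.samples_of_type("calibrator")
        analytes = t.analyte_ids()
        dil = t.somamer_meta.loc[analytes, "dilution_set"]
        ref = t.rfu.loc[cal, analytes].median(axis=0)  # defining reference
        out, _ = intraplate_median_normalize(t)
        for s in cal:
            for d in (1, 2, 3):
                cols = analytes[dil == d]
                ratios = ref[cols] / out.rfu.loc[s, cols]
                assert np.median(ratios) == pytest.approx(1.0, abs=1e-12)


class TestReferenceAndPlateScale:
    def test_single_calibrator_reference_is_itself(self):
        t = make_table([[3.0, 7.0]], sample_type=["calibrator"])
        ref = build_global_reference(t)
        assert list(ref.calibrator_ref) == [3.0, 7.0]

    def test_two_calibrators_median_midpoint(self):
        t = make_table([[3.0, 1.0], [5.0, 9.0]], sample_type=["calibrator"] * 2)
        ref = build_global_reference(t)
        assert list(ref.calibrator_ref) == [4.0, 5.0]

    def test_pooled_median_matches_brute_force(self):
        rng = np.random.default_rng(3)
        rfu = rng.lognormal(7, 1, size=(9, 6))
        t = make_table(rfu, sample_type=["calibrator"] * 9,
                       plate=["P1"] * 3 + ["P2"] * 3 + ["P3"] * 3)
        ref = build_global_reference(t)
        assert np.allclose(ref.calibrator_ref, np.median(rfu, axis=0))

    def test_no_calibrators_errors(self):
        t = make_table([[1.0, 2.0]])
        with pytest.raises(ValueError, match="calibrator"):
            build_global_reference(t)

    def test_plate_matching_reference_has_unit_factor(self):
        rfu = np.array([[2.0, 6.0], [2.0, 6.0], [5.0, 5.0]])
        t = make_table(rfu, sample_type=["calibrator", "calibrator", "study"])
        ref = build_global_reference(t)
        out, f = plate_scale(t, ref)
        assert f.plate_scale["P1"] == pytest.approx(1.0)
        assert np.allclose(out.rfu, rfu)

    def test_plate_at_twice_reference_gets_half(self):
        rfu = np.array([[2.0, 6.0], [2.0, 6.0]])
        t = make_table(rfu, sample_type=["calibrator"] * 2)
        ref = build_global_reference(t)
        t2 = make_table(rfu * 2.0, sample_type=["calibrator"] * 2)
        out, f = plate_scale(t2, ref)
        assert f.plate_scale["P1"] == pytest.approx(0.5)
        assert np.allclose(out.rfu, rfu)


class TestCalibrate:
    def test_plate_equal_to_reference_all_unit(self):
        rfu = np.array([[2.0, 6.0], [2.0, 6.0], [3.0, 9.0]])
        t = make_table(rfu, sample_type=["calibrator", "calibrator", "study"])
        ref = build_global_reference(t)
        out, f = calibrate(t, ref)
        assert np.allclose(f.calibration.to_numpy(), 1.0)
        assert np.allclose(out.rfu, rfu)

    def test_somamer_at_twice_reference_halved_and_aligned(self):
        base = np.array([[2.0, 6.0], [2.0, 6.0]])
        t = make_table(base, sample_type=["calibrator"] * 2)
        ref = build_global_reference(t)
        skew = base.copy()
        skew[:, 0] *= 2.0  # one SOMAmer reads double
        t2 = make_table(skew, sample_type=["calibrator"] * 2)
        out, f = calibrate(t2, ref)
        assert f.calibration.loc["P1", "SM0"] == pytest.approx(0.5)
        cal_medians = out.rfu.median(axis=0)
        assert np.allclose(cal_medians, ref.calibrator_ref)

    def test_factors_after_perfect_plate_scale_have_median_one(self):
        rng = np.random.default_rng(4)
        t = _plate_with_controls(rng)
        t1, _ = hybridization_normalize(t)
        t2, _ = intraplate_median_normalize(t1)
        ref = build_global_reference(t2)
        t3, _ = plate_scale(t2, ref)
        _, f = calibrate(t3, ref)
        med = np.median(f.calibration.loc["P1"].to_numpy())
        assert med == pytest.approx(1.0, abs=1e-12)


class TestMedianNormalize:
    def test_sample_equal_to_reference_unit_factor(self):
        rfu = np.array([[2.0, 6.0], [2.0, 6.0], [2.0, 6.0]])
        t = make_table(rfu, sample_type=["calibrator", "calibrator", "study"])
        ref = build_global_reference(t)
        out, f = median_normalize_to_reference(t, ref)
        assert np.allclose(f.ref_median["factor"], 1.0)

    def test_scaled_sample_gets_reciprocal_factor(self):
        rfu = np.array([[2.0, 6.0], [2.0, 6.0], [6.0, 18.0]])
        t = make_table(rfu, sample_type=["calibrator", "calibrator", "study"])
        ref = build_global_reference(t)
        out, f = median_normalize_to_reference(t, ref)
        fac = f.ref_median.set_index("sample_id")["factor"]
        assert fac["S2"] == pytest.approx(1 / 3)
        assert np.allclose(out.rfu.loc["S2"], [2.0, 6.0])

    def test_hand_fixture_vs_brute_force_median_of_ratios(self):
        rng = np.random.default_rng(5)
        rfu = rng.lognormal(6, 1, size=(4, 9))
        dil = [1, 1, 1, 2, 2, 2, 3, 3, 3]
        t = make_table(rfu, dilution=dil,
                       sample_type=["calibrator", "study", "qc", "study"])
        ref = build_global_reference(t)
        out, f = median_normalize_to_reference(t, ref)
        for s in ("S1", "S2", "S3"):
            for d in (1, 2, 3):
                cols = [f"SM{j}" for j in range(9) if dil[j] == d]
                expect = np.median(ref.normalization_ref[cols] / t.rfu.loc[s, cols])
                got = f.ref_median.query("sample_id == @s and dilution_set == @d")["factor"].iloc[0]
                assert got == pytest.approx(expect, rel=1e-12)

    def test_empty_group_noop_with_warning(self):
        t = make_table([[1.0, 2.0]], sample_type=["calibrator"])
        ref = build_global_reference(t)
        with pytest.warns(UserWarning):
            out, f = median_normalize_to_reference(t, ref)
        assert np.allclose(out.rfu, t.rfu)


class TestQcReport:
    def test_all_unit_factors_pass(self):
        f = NormFactors(
            hyb=pd.Series([1.0, 1.0]),
            plate_scale=pd.Series([1.0]),
            qc_ratios=pd.DataFrame(np.ones((2, 10))),
        )
        rep = qc_report(f)
        assert rep.overall_pass and rep.qc_fraction_in_band == 1.0

    def test_85_percent_rule_boundary(self):
        ratios = np.ones(100)
        ratios[:16] = 2.0  # 84% inside -> fail
        rep = qc_report(NormFactors(qc_ratios=pd.DataFrame(ratios[None, :])))
        assert not rep.qc_pass
        ratios[:14] = 2.0
        ratios[14:16] = 1.0  # 86% inside -> pass
        rep = qc_report(NormFactors(qc_ratios=pd.DataFrame(ratios[None, :])))
        assert rep.qc_pass

    def test_factor_out_of_band_fails_class(self):
        rep = qc_report(NormFactors(hyb=pd.Series([1.0, 3.0])))
        assert not rep.factor_checks["hybridization"][1]
        assert not rep.overall_pass


class TestPipeline:
    def _clean_cfg(self, **kw):
        base = dict(n_patients=40, n_somamers=60, removal_count=4, dup2_count=3,
                    dup3_count=1, n_plates=2, calibrators_per_plate=3,
                    qc_per_plate=2, buffer_per_plate=1, n_informative=5, seed=21)
        base.update(kw)
        return SimConfig(**base)

    def test_clean_simulation_passes_report(self):
        coh = simulate_cohort(self._clean_cfg())
        _, factors, rep = normalize_pipeline(coh.somamer_table)
        assert rep.overall_pass, rep.to_dict()
        assert (factors.plate_scale >= 0.4).all() and (factors.plate_scale <= 2.5).all()

    def test_deterministic_across_reruns(self):
        coh = simulate_cohort(self._clean_cfg())
        t1, f1, _ = normalize_pipeline(coh.somamer_table)
        t2, f2, _ = normalize_pipeline(coh.somamer_table)
        pd.testing.assert_frame_equal(t1.rfu, t2.rfu)
        pd.testing.assert_series_equal(f1.hyb, f2.hyb)

    def test_second_pass_factors_are_unit_on_noise_free_data(self):
        # with no measurement noise the chain is exactly idempotent for the
        # hybridization, intraplate, plate-scale and calibration factors
        coh = simulate_cohort(self._clean_cfg(noise_sd=0.0))
        t1, _, _ = normalize_pipeline(coh.somamer_table)
        _, f2, _ = normalize_pipeline(t1)
        assert np.allclose(f2.hyb, 1.0, atol=1e-9)
        assert np.allclose(f2.intraplate["factor"], 1.0, atol=1e-9)
        assert np.allclose(f2.plate_scale, 1.0, atol=1e-9)
        assert np.allclose(f2.calibration.to_numpy(), 1.0, atol=1e-9)

    def test_uniform_steps_preserve_order_within_sample(self):
        # hybridization normalization and plate scaling multiply every
        # value in a sample by one positive factor: ordering is exact
        coh = simulate_cohort(self._clean_cfg())
        t0 = coh.somamer_table
        t1, _ = hybridization_normalize(t0)
        ref = build_global_reference(t1)
        t2, _ = plate_scale(t1, ref)
        s = t0.samples_of_type("study")[0]
        order0 = np.argsort(t0.rfu.loc[s].to_numpy())
        assert (np.argsort(t1.rfu.loc[s].to_numpy()) == order0).all()
        assert (np.argsort(t2.rfu.loc[s].to_numpy()) == order0).all()
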