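"""The piecewise-linear mapping eta, whole-volume standardization, and chains."""

import numpy as np
import pytest

from petstd import (LandmarkSet, MappingSpec, Modality, PhantomConfig,
                    ScanMeta, StandardScale, ac_to_suv, calibrate, cv_metric,
                    eta, generate_cohort, organ_mean, run_strategy,
                    standardize)
from petstd.exceptions import ModalityError

from conftest import make_volume
from oracle_utils import eta_oracle


def _spec(p_alpha=0.0, p_m=10.0, p_beta=30.0, s_m=4.0, s_max=10.0):
    lm = LandmarkSet(i_min=p_alpha, p_alpha=p_alpha, p_m=p_m, p_beta=p_beta,
                     i_max=p_beta + 100, alpha=0.0, beta=95.0)
    scale = StandardScale(s_m=s_m, s_max=s_max, beta=95.0, inv_scale=1.0,
                          modality=Modality.SUV, calibration_n=2,
                          reference_organ="liver")
    return MappingSpec(landmarks=lm, scale=scale)


class TestEta:
    def test_landmark_fixed_points(self):
        spec = _spec()
        assert eta(0.0, spec) == 0.0      # p_alpha -> s_min
        assert eta(10.0, spec) == 4.0     # p_m -> s_m
        assert eta(30.0, spec) == 10.0    # p_beta -> s_max

    @pytest.mark.parametrize("x,expected", [(5.0, 2.0), (20.0, 7.0), (40.0, 13.0)])
    def test_hand_evaluated_segments_and_upper_extrapolation(self, x, expected):
        assert eta(x, _spec()) == pytest.approx(expected, rel=1e-12)

    def test_extrapolates_below_p_alpha_with_first_slope(self):
        spec = _spec(p_alpha=2.0, p_m=10.0, p_beta=30.0)
        # slope1 = 4/8 = 0.5; x = 0 -> 0.5*(0-2) = -1
        assert eta(0.0, spec) == pytest.approx(-1.0, rel=1e-12)

    def test_strictly_increasing_and_continuous_at_pm(self):
        spec = _spec()
        xs = np.linspace(-5, 60, 501)
        ys = eta(xs, spec)
        assert np.all(np.diff(ys) > 0)
        assert eta(10.0 - 1e-9, spec) == pytest.approx(eta(10.0 + 1e-9, spec), abs=1e-6)

    def test_matches_scalar_oracle(self):
        spec = _spec(p_alpha=1.0, p_m=7.0, p_beta=22.0, s_m=3.0, s_max=9.0)
        xs = np.linspace(0, 50, 97)
        expected = [eta_oracle(x, 1.0, 7.0, 22.0, 0.0, 3.0, 9.0) for x in xs]
        np.testing.assert_allclose(eta(xs, spec), expected, rtol=1e-12)


@pytest.fixture(scope="module")
def calibrated():
    cfg = PhantomConfig.suv_default()
    samples = generate_cohort(cfg, 8, seed=51)
    scale = calibrate([s.volume for s in samples],
                      [s.masks["liver"] for s in samples])
    return cfg, samples, scale


class TestStandardize:

    def test_body_median_maps_to_inv_scale_times_sm(self, calibrated):
        from petstd import extract_landmarks
        cfg, samples, scale = calibrated
        vol = samples[0].volume
        lm = extract_landmarks(vol, scale.beta)
        out = standardize(vol, scale)
        spec = MappingSpec(landmarks=lm, scale=scale)
        assert float(scale.inv_scale * eta(lm.p_m, spec)) == pytest.approx(
            scale.inv_scale * scale.s_m, rel=1e-9)
        # landmark images map exactly: check through the volume at a voxel
        i = np.argmin(np.abs(vol.voxels - lm.p_m))
        assert out.voxels.flat[i] == pytest.approx(
            scale.inv_scale * eta(vol.voxels.flat[i], spec), rel=1e-12)

    def test_gain_invariance_for_min_zero_images(self, calibrated):
        cfg, samples, scale = calibrated
        vol = samples[1].volume
        assert vol.voxels.min() == 0.0
        out1 = standardize(vol, scale)
        out2 = standardize(vol.with_voxels(3.7 * vol.voxels), scale)
        np.testing.assert_allclose(out2.voxels, out1.voxels, rtol=1e-6)

    def test_voxelwise_match_against_plain_loop(self, calibrated):
        from petstd import extract_landmarks
        cfg, samples, scale = calibrated
        small = PhantomConfig.suv_default(grid_shape=(16, 16, 16))
        vol = generate_cohort(small, 2, seed=52)[0].volume
        out = standardize(vol, scale)
        lm = extract_landmarks(vol, scale.beta)
        expected = np.empty_like(vol.voxels)
        for idx, x in np.ndenumerate(vol.voxels):
            expected[idx] = scale.inv_scale * eta_oracle(
                float(x), lm.p_alpha, lm.p_m, lm.p_beta,
                scale.s_min, scale.s_m, scale.s_max)
        np.testing.assert_allclose(out.voxels, expected, rtol=1e-10)

    def test_rank_order_preserved_exactly(self, calibrated):
        cfg, samples, scale = calibrated
        vol = samples[2].volume
        out = standardize(vol, scale)
        assert np.array_equal(np.argsort(vol.voxels.ravel(), kind="stable"),
                              np.argsort(out.voxels.ravel(), kind="stable"))

    def test_landmarks_map_to_scale_positions(self, calibrated):
        from petstd import extract_landmarks
        cfg, samples, scale = calibrated
        vol = samples[3].volume
        lm = extract_landmarks(vol, scale.beta)
        spec = MappingSpec(landmarks=lm, scale=scale)
        got = scale.inv_scale * eta(np.array([lm.p_alpha, lm.p_m, lm.p_beta]), spec)
        expected = scale.inv_scale * np.array([scale.s_min, scale.s_m, scale.s_max])
        np.testing.assert_allclose(got, expected, rtol=1e-9, atol=1e-12)

    def test_modality_tagging_and_mismatch(self, calibrated):
        cfg, samples, scale = calibrated
        out = standardize(samples[0].volume, scale)
        assert out.modality is Modality.STD_SUV
        ac_vol = make_volume(samples[0].volume.voxels, modality=Modality.AC)
        with pytest.raises(ModalityError):
            standardize(ac_vol, scale)


@pytest.fixture(scope="module")
def ac_setup():
    cfg = PhantomConfig.ac_default()
    test = generate_cohort(cfg, 4, seed=61)
    calib = generate_cohort(cfg, 6, seed=62)
    metas = [ScanMeta(injected_dose_mbq=400.0, body_weight_g=75000.0,
                      subject_id=f"t{i}") for i in range(4)]
    cmetas = [ScanMeta(injected_dose_mbq=380.0, body_weight_g=70000.0,
                       subject_id=f"c{i}") for i in range(6)]
    return cfg, test, calib, metas, cmetas


class TestRunStrategy:

    def test_single_standardization_step(self, ac_setup):
        cfg, test, calib, metas, cmetas = ac_setup
        out, scales = run_strategy(["s-AC"], [s.volume for s in test],
                                   calib_images=[s.volume for s in calib],
                                   calib_organ_masks=[s.masks["liver"] for s in calib])
        scale = calibrate([s.volume for s in calib], [s.masks["liver"] for s in calib])
        direct = standardize(test[0].volume, scale)
        np.testing.assert_allclose(out[0].voxels, direct.voxels, rtol=1e-12)
        assert len(scales) == 1 and scales[0].beta == scale.beta

    def test_sac_then_suv_equals_composition(self, ac_setup):
        cfg, test, calib, metas, cmetas = ac_setup
        out, _ = run_strategy("s-AC,SUV", [s.volume for s in test], metas,
                              calib_images=[s.volume for s in calib],
                              calib_organ_masks=[s.masks["liver"] for s in calib],
                              calib_metas=cmetas)
        scale = calibrate([s.volume for s in calib], [s.masks["liver"] for s in calib])
        expected = ac_to_suv(standardize(test[1].volume, scale), metas[1])
        np.testing.assert_allclose(out[1].voxels, expected.voxels, rtol=1e-12)
        assert out[1].modality is Modality.SUV

    def test_suv_step_alone_is_ac_to_suv(self, ac_setup):
        cfg, test, calib, metas, cmetas = ac_setup
        out, scales = run_strategy(["SUV"], [s.volume for s in test], metas)
        np.testing.assert_allclose(out[2].voxels,
                                   ac_to_suv(test[2].volume, metas[2]).voxels)
        assert scales == []

    def test_ill_typed_chain_rejected(self, ac_setup):
        cfg, test, calib, metas, cmetas = ac_setup
        with pytest.raises(ModalityError):
            run_strategy(["SUV", "SUV"], [s.volume for s in test], metas)
        with pytest.raises(ModalityError):
            run_strategy(["s-SUV"], [s.volume for s in test],
                         calib_images=[s.volume for s in calib],
                         calib_organ_masks=[s.masks["liver"] for s in calib])

    def test_second_standardization_recalibrates(self, ac_setup):
        cfg, test, calib, metas, cmetas = ac_setup
        out, scales = run_strategy(["s-AC", "s-AC"], [s.volume for s in test],
                                   calib_images=[s.volume for s in calib],
                                   calib_organ_masks=[s.masks["liver"] for s in calib])
        assert len(scales) == 2
        # the second scale was estimated on the standardized calibration set,
        # so its landmarks live on the standardized value range
        assert scales[1].inv_scale != scales[0].inv_scale
        assert out[0].modality is Modality.STD_AC
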