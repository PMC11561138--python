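import numpy as np
import pytest

import kneeload.synthetic as syn
from kneeload.errors import (
    CalibrationError,
    InsufficientDataError,
    LowQualityError,
)
from kneeload.timeseries import KeypointSeries
from kneeload.video_pipeline import (
    CameraScale,
    estimate_kfa_predictor_vc,
    estimate_kfa_series_vc,
    estimate_scale,
    estimate_walking_speed_vc,
)

LANDMARKS = ("Nose", "MidHip", "RHip", "RKnee", "RAnkle",
             "LHip", "LKnee", "LAnkle")


def make_series(frames: dict[str, np.ndarray], fs=100.0,
                image_size=(480, 272)) -> KeypointSeries:
    points = {}
    n = len(next(iter(frames.values())))
    for name in LANDMARKS:
        points[name] = np.asarray(
            frames.get(name, np.zeros((n, 3))), dtype=float
        )
    return KeypointSeries(points=points, fs=fs, image_size=image_size)


def constant_pose(n, hip=(240, 100), knee=(240, 150), ankle=(240, 200),
                  conf=0.9):
    frames = {}
    for name, xy in (("MidHip", hip), ("RHip", hip), ("LHip", hip),
                     ("RKnee", knee), ("LKnee", knee),
                     ("RAnkle", ankle), ("LAnkle", ankle),
                     ("Nose", (hip[0], 20))):
        frames[name] = np.tile([*xy, conf], (n, 1))
    return frames


class TestScale:
    def test_override_returned_verbatim(self, trial_noisefree):
        scale = estimate_scale(trial_noisefree.keypoints, 175.0, override=0.004)
        assert scale.metres_per_pixel == 0.004

    def test_known_camera_recovered_within_3_percent(self, profile,
                                                     clean_load_model):
        cam = syn.CameraConfig(metres_per_pixel=0.005, image_size=(960, 544))
        tr = syn.make_trial(profile, "comfortable", "right", seed=21,
                            load_model=clean_load_model, camera=cam)
        scale = estimate_scale(tr.keypoints, profile.height)
        assert scale.metres_per_pixel == pytest.approx(0.005, rel=0.03)

    def test_low_confidence_series_rejected(self):
        frames = constant_pose(50, conf=0.1)
        with pytest.raises(CalibrationError):
            estimate_scale(make_series(frames), 175.0)


class TestWalkingSpeed:
    def test_two_pixels_per_frame_exact(self):
        n = 120
        frames = constant_pose(n)
        x = 100 + 2.0 * np.arange(n)
        for name in ("MidHip", "RHip", "LHip"):
            frames[name] = np.column_stack([x, np.full(n, 100.0),
                                            np.full(n, 0.9)])
        speed = estimate_walking_speed_vc(
            make_series(frames), CameraScale(0.005)
        )
        # 2 px/frame * 100 Hz * 0.005 m/px = 1 m/s.
        assert speed == pytest.approx(100.0, rel=1e-6)

    def test_stationary_hip_zero_speed(self):
        frames = constant_pose(60)
        speed = estimate_walking_speed_vc(make_series(frames), CameraScale(0.005))
        assert speed == pytest.approx(0.0, abs=1e-9)

    def test_too_few_confident_frames(self):
        frames = constant_pose(8)
        with pytest.raises(InsufficientDataError):
            estimate_walking_speed_vc(make_series(frames), CameraScale(0.005))

    def test_simulated_trial_within_two_percent(self, trial_noisefree):
        scale = estimate_scale(trial_noisefree.keypoints,
                               trial_noisefree.subject.height)
        speed = estimate_walking_speed_vc(trial_noisefree.keypoints, scale)
        assert speed == pytest.approx(trial_noisefree.true_speed, rel=0.02)

    def test_mirroring_invariance(self, trial_noisefree):
        """Walking direction on screen must not matter."""
        kps = trial_noisefree.keypoints
        w = kps.image_size[0]
        mirrored_points = {}
        for name, arr in kps.points.items():
            m = arr.copy()
            vis = m[:, 2] > 0
            m[vis, 0] = w - m[vis, 0]
            mirrored_points[name] = m
        mirrored = KeypointSeries(points=mirrored_points, fs=kps.fs,
                                  image_size=kps.image_size)
        scale = CameraScale(0.009)
        v0 = estimate_walking_speed_vc(kps, scale)
        v1 = estimate_walking_speed_vc(mirrored, scale)
        assert v1 == pytest.approx(v0, rel=1e-6)
        k0 = estimate_kfa_predictor_vc(kps)
        k1 = estimate_kfa_predictor_vc(mirrored)
        assert k1 == pytest.approx(k0, abs=1e-6)


class TestKfaSeries:
    def test_collinear_points_full_extension(self):
        frames = constant_pose(40)  # hip, knee, ankle on a vertical line
        curve = estimate_kfa_series_vc(make_series(frames), smooth_window=0)
        np.testing.assert_allclose(curve.angle, 0.0, atol=1e-4)

    def test_hand_geometry_45_degrees(self):
        """knee->hip = (0,-1), knee->ankle = (1,1): included angle 135deg,
        flexion 45deg."""
        frames = constant_pose(
            40, hip=(100, 99), knee=(100, 100), ankle=(101, 101)
        )
        curve = estimate_kfa_series_vc(make_series(frames), smooth_window=0)
        np.testing.assert_allclose(curve.angle, 45.0, atol=1e-9)

    def test_low_confidence_frames_interpolated(self):
        frames = constant_pose(
            60, hip=(100, 99), knee=(100, 100), ankle=(101, 101)
        )
        # Corrupt a confident-looking block with garbage at low confidence.
        frames["RKnee"][20:30] = [999.0, 999.0, 0.05]
        curve = estimate_kfa_series_vc(make_series(frames), smooth_window=0)
        np.testing.assert_allclose(curve.angle, 45.0, atol=1e-9)

    def test_majority_low_confidence_rejected(self):
        frames = constant_pose(60)
        frames["RKnee"][:, 2] = 0.05
        with pytest.raises(LowQualityError):
            estimate_kfa_series_vc(make_series(frames))

    def test_scaling_translation_invariance(self):
        base = constant_pose(40, hip=(100, 80), knee=(105, 120),
                             ankle=(100, 160))
        s0 = estimate_kfa_series_vc(make_series(base), smooth_window=0)
        moved = {
            k: np.column_stack([v[:, 0] * 3 + 50, v[:, 1] * 3 - 10, v[:, 2]])
            for k, v in base.items()
        }
        s1 = estimate_kfa_series_vc(make_series(moved), smooth_window=0)
        np.testing.assert_allclose(s1.angle, s0.angle, atol=1e-9)

    def test_matches_truth_noise_free(self, trial_noisefree):
        kin = trial_noisefree.kinematics
        curve = estimate_kfa_series_vc(trial_noisefree.keypoints)
        w = kin.stance_truth
        err = curve.angle[w.slice()] - kin.flexion_deg["right"][w.slice()]
        assert np.sqrt(np.mean(err**2)) <= 0.5


class TestOcclusion:
    def test_error_monotone_in_bias_speed_unaffected(self, profile):
        """Biasing occluded far-leg keypoints degrades the KFA predictor but
        not the hip-based speed estimate."""
        kfa_errs, sp_errs = [], []
        for bias in (0.0, 4.0, 12.0):
            noise = syn.NoiseProfile(name="occ", occlusion=True,
                                     occlusion_bias_px=bias)
            ke, se = [], []
            for s in range(3):
                tr = syn.make_trial(profile, "comfortable", "left",
                                    seed=500 + s, noise=noise)
                ke.append(abs(estimate_kfa_predictor_vc(tr.keypoints)
                              - tr.kfa_predictor_truth))
                scale = estimate_scale(tr.keypoints, profile.height)
                se.append(abs(estimate_walking_speed_vc(tr.keypoints, scale)
                              - tr.true_speed) / tr.true_speed)
            kfa_errs.append(np.mean(ke))
            sp_errs.append(np.mean(se))
        assert kfa_errs[0] <= kfa_errs[1] <= kfa_errs[2]
        assert max(sp_errs) < 0.02
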