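import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import kneeload.synthetic as syn
from kneeload.errors import InsufficientCyclesError, MissingStreamError
from kneeload.imu_pipeline import (
    GaitCycleEvents,
    SegmentChainConfig,
    detect_gait_cycles,
    estimate_kfa_predictor_imu,
    estimate_kfa_series_imu,
    estimate_walking_speed_imu,
)
from kneeload.timeseries import ImuStream


def make_stream(site, quat, accel, fs=100.0):
    n = len(quat)
    return ImuStream(site=site, time=np.arange(n) / fs,
                     quat=np.asarray(quat), accel=np.asarray(accel))


def planar_rotation_stream(site, angles_deg, axis=(0, 0, 1)):
    rot = Rotation.from_rotvec(
        np.deg2rad(np.asarray(angles_deg))[:, None] * np.asarray(axis)
    )
    n = len(angles_deg)
    return make_stream(site, rot.as_quat(scalar_first=True), np.zeros((n, 3)))


class TestGaitCycleDetection:
    def test_period_recovered_from_simulation(self, trial_noisefree):
        events = detect_gait_cycles(trial_noisefree.imu["shank_r"])
        assert events.gait_period == pytest.approx(
            trial_noisefree.kinematics.gait_period, abs=0.02
        )

    def test_constant_acceleration_rejected(self):
        n = 400
        quat = np.tile([1.0, 0, 0, 0], (n, 1))
        accel = np.tile([0.0, 9.81, 0.0], (n, 1))
        with pytest.raises(InsufficientCyclesError):
            detect_gait_cycles(make_stream("shank_r", quat, accel))

    def test_too_short_recording_rejected(self):
        quat = np.tile([1.0, 0, 0, 0], (50, 1))
        with pytest.raises(InsufficientCyclesError):
            detect_gait_cycles(make_stream("shank_r", quat, np.zeros((50, 3))))

    def test_doubling_cadence_halves_period(self, profile):
        periods = {}
        for T in (1.3, 0.65):
            cfg = syn.KinematicsConfig(gait_period=T)
            kin = syn.synthesize_kinematics(profile, "comfortable", "right",
                                            seed=3, config=cfg)
            streams = syn.render_imu(kin, seed=0)
            periods[T] = detect_gait_cycles(streams["shank_r"]).gait_period
        assert periods[0.65] / periods[1.3] == pytest.approx(0.5, abs=0.05)


class TestWalkingSpeed:
    def test_recovers_true_speed_noise_free(self, trial_noisefree):
        speed = estimate_walking_speed_imu(
            trial_noisefree.imu, trial_noisefree.subject.height
        )
        assert speed == pytest.approx(trial_noisefree.true_speed, rel=0.05)

    def test_missing_sensor_site_raises(self, trial_noisefree):
        streams = {k: v for k, v in trial_noisefree.imu.items() if k != "thigh_l"}
        with pytest.raises(MissingStreamError):
            estimate_walking_speed_imu(streams, trial_noisefree.subject.height)

    def test_zero_motion_propagates_insufficient_cycles(self):
        n = 400
        quat = np.tile([1.0, 0, 0, 0], (n, 1))
        accel = np.tile([0.0, 9.81, 0.0], (n, 1))
        streams = {
            site: make_stream(site, quat, accel)
            for site in ("thigh_l", "thigh_r", "shank_l", "shank_r")
        }
        with pytest.raises(InsufficientCyclesError):
            estimate_walking_speed_imu(streams, 175.0)

    def test_time_dilation_halves_speed(self, trial_noisefree):
        """Same orientations over twice the time -> half the speed
        (event indices fixed, so this isolates the stride/period arithmetic)."""
        dilated = {
            site: ImuStream(site=site, time=s.time * 2.0, quat=s.quat,
                            accel=s.accel)
            for site, s in trial_noisefree.imu.items()
        }
        events = {
            "left": detect_gait_cycles(trial_noisefree.imu["shank_l"]),
            "right": detect_gait_cycles(trial_noisefree.imu["shank_r"]),
        }
        dilated_events = {
            leg: GaitCycleEvents(indices=ev.indices,
                                 gait_period=2.0 * ev.gait_period)
            for leg, ev in events.items()
        }
        h = trial_noisefree.subject.height
        v = estimate_walking_speed_imu(trial_noisefree.imu, h, events=events)
        v2 = estimate_walking_speed_imu(dilated, h, events=dilated_events)
        assert v2 == pytest.approx(v / 2.0, rel=0.02)

    def test_invariant_to_global_rotation(self, trial_noisefree):
        """A world-frame change (arbitrary rigid rotation applied to every
        orientation) must not change the speed estimate."""
        g = Rotation.from_rotvec([0.4, -1.1, 0.7])
        rotated = {}
        for site, s in trial_noisefree.imu.items():
            r = Rotation.from_quat(s.quat, scalar_first=True)
            q = (g * r).as_quat(scalar_first=True)
            rotated[site] = ImuStream(site=site, time=s.time, quat=q,
                                      accel=s.accel)
        v0 = estimate_walking_speed_imu(trial_noisefree.imu,
                                        trial_noisefree.subject.height)
        v1 = estimate_walking_speed_imu(rotated, trial_noisefree.subject.height)
        assert v1 == pytest.approx(v0, rel=1e-6)


class TestKfaFromImu:
    def test_identical_rotations_give_zero(self):
        angles = 30 * np.sin(np.linspace(0, 4 * np.pi, 300))
        thigh = planar_rotation_stream("thigh_r", angles)
        shank = planar_rotation_stream("shank_r", angles)
        curve = estimate_kfa_series_imu(thigh, shank)
        np.testing.assert_allclose(curve.angle, 0.0, atol=1e-9)

    def test_pure_shank_rotation_recovered(self):
        """Shank rotating to 30 degrees about the flexion axis while the
        thigh stays fixed reads as 30 degrees of flexion."""
        ramp = np.concatenate([np.zeros(10), np.linspace(0, 30, 290)])
        thigh = planar_rotation_stream("thigh_r", np.zeros(300))
        shank = planar_rotation_stream("shank_r", ramp)
        curve = estimate_kfa_series_imu(thigh, shank)
        assert abs(curve.angle[-1]) == pytest.approx(30.0, abs=1e-6)

    def test_series_matches_truth_noise_free(self, trial_noisefree):
        kin = trial_noisefree.kinematics
        curve = estimate_kfa_series_imu(
            trial_noisefree.imu["thigh_r"], trial_noisefree.imu["shank_r"]
        )
        rmse = np.sqrt(np.mean((curve.angle - kin.flexion_deg["right"]) ** 2))
        assert rmse <= 1.0

    def test_predictor_recovered_within_one_degree(self, trial_noisefree):
        kfa = estimate_kfa_predictor_imu(trial_noisefree.imu)
        assert kfa == pytest.approx(trial_noisefree.kfa_predictor_truth, abs=1.0)

    def test_motionless_pair_flat_zero(self):
        thigh = planar_rotation_stream("thigh_r", np.zeros(300))
        shank = planar_rotation_stream("shank_r", np.zeros(300))
        curve = estimate_kfa_series_imu(thigh, shank)
        np.testing.assert_allclose(curve.angle, 0.0)


def test_segment_chain_config_validation():
    with pytest.raises(Exception):
        SegmentChainConfig(thigh_fraction=0.7)


def test_events_validation():
    with pytest.raises(Exception):
        GaitCycleEvents(indices=np.array([5, 3]), gait_period=1.0)
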