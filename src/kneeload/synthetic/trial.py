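"""Trial assembly: kinematics + loads + sensors + camera + validity.

A trial is one overground walking pass of one subject under one walking
configuration (instructed velocity x direction). ``simulate_trials`` yields
the standard study layout: three instructed velocities (comfortable and
+/- 25%) times two directions, K trials each. ``generate_training_table``
is the fast path used to build regression training data: it draws the same
speed/flexion-template/load distributions but skips sensor rendering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..timeseries import FlexionCurve, KeypointSeries, StanceWindow
from .camera import CameraConfig, render_keypoints
from .cohort import SubjectProfile
from .kinematics import (
    VELOCITY_FACTORS,
    KinematicsConfig,
    TrialKinematics,
    sample_template_params,
    synthesize_kinematics,
)
from .loads import GenerativeLoadModel, SynthesizedLoad, synthesize_kjcf
from .noise import NOISE_NONE, NoiseProfile
from .sensors import render_imu

VELOCITY_CLASSES = ("slow", "comfortable", "fast")
DIRECTIONS = ("left", "right")
#: The six walking configurations, in deterministic order.
CONFIGURATIONS = tuple(
    (v, d) for v in VELOCITY_CLASSES for d in DIRECTIONS
)


@dataclass
class SyntheticTrial:
    """One simulated walking trial with full ground truth."""

    subject: SubjectProfile
    velocity_class: str
    direction: str
    trial_index: int
    kinematics: TrialKinematics
    load: SynthesizedLoad
    imu: dict | None
    keypoints: KeypointSeries | None
    valid: bool

    @property
    def subject_id(self) -> str:
        return self.subject.subject_id

    @property
    def true_speed(self) -> float:
        return self.kinematics.true_speed

    @property
    def kfa_predictor_truth(self) -> float:
        return self.kinematics.kfa_predictor_truth

    @property
    def stance_truth(self) -> StanceWindow:
        return self.kinematics.stance_truth

    @property
    def flexion_truth(self) -> FlexionCurve:
        return self.kinematics.flexion_truth()


def make_trial(
    profile: SubjectProfile,
    velocity_class: str,
    direction: str,
    seed: int | np.random.SeedSequence,
    trial_index: int = 0,
    load_model: GenerativeLoadModel | None = None,
    noise: NoiseProfile = NOISE_NONE,
    camera: CameraConfig | None = None,
    kinematics_config: KinematicsConfig | None = None,
    with_imu: bool = True,
    with_video: bool = True,
) -> SyntheticTrial:
    """Simulate one trial; bit-reproducible for a fixed seed."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    kin_seed, load_seed, imu_seed, cam_seed, valid_seed = ss.spawn(5)
    model = load_model or GenerativeLoadModel()

    kin = synthesize_kinematics(
        profile, velocity_class, direction, kin_seed, config=kinematics_config
    )
    load = synthesize_kjcf(
        profile,
        kin.true_speed,
        kin.kfa_predictor_truth,
        model,
        load_seed,
        n_samples=len(kin.stance_truth),
    )
    imu = render_imu(kin, noise=noise, seed=imu_seed) if with_imu else None
    kps = (
        render_keypoints(kin, camera=camera, noise=noise, seed=cam_seed)
        if with_video
        else None
    )
    valid = bool(np.random.default_rng(valid_seed).random() >= noise.p_invalid)
    if load.degenerate:
        valid = False
    return SyntheticTrial(
        subject=profile,
        velocity_class=velocity_class,
        direction=direction,
        trial_index=trial_index,
        kinematics=kin,
        load=load,
        imu=imu,
        keypoints=kps,
        valid=valid,
    )


def simulate_trials(
    cohort: list[SubjectProfile],
    trials_per_config: int,
    seed: int,
    load_model: GenerativeLoadModel | None = None,
    noise: NoiseProfile = NOISE_NONE,
    camera: CameraConfig | None = None,
    kinematics_config: KinematicsConfig | None = None,
    with_imu: bool = True,
    with_video: bool = True,
):
    """Yield trials for a whole cohort in deterministic study order."""
    root = np.random.SeedSequence(seed)
    subject_seeds = root.spawn(len(cohort))
    for profile, sseed in zip(cohort, subject_seeds):
        trial_seeds = iter(sseed.spawn(len(CONFIGURATIONS) * trials_per_config))
        for velocity_class, direction in CONFIGURATIONS:
            for k in range(trials_per_config):
                yield make_trial(
                    profile,
                    velocity_class,
                    direction,
                    next(trial_seeds),
                    trial_index=k,
                    load_model=load_model,
                    noise=noise,
                    camera=camera,
                    kinematics_config=kinematics_config,
                    with_imu=with_imu,
                    with_video=with_video,
                )


def generate_training_table(
    cohort: list[SubjectProfile],
    trials_per_subject: int,
    seed: int,
    load_model: GenerativeLoadModel | None = None,
    speed_jitter: float = 0.02,
) -> pd.DataFrame:
    """Fast (no sensor rendering) training dataset of predictor/peak pairs.

    Walking speed cycles through the three instructed velocities with a small
    per-trial multiplicative jitter; the KFA predictor is drawn from the same
    flexion-template distribution the full simulator uses; peaks come from
    the generative load model with its peak noise.
    """
    model = load_model or GenerativeLoadModel()
    root = np.random.SeedSequence([seed, 0x7A1])
    rows = []
    for profile, sseed in zip(cohort, root.spawn(len(cohort))):
        rng = np.random.default_rng(sseed)
        for k in range(trials_per_subject):
            vclass = VELOCITY_CLASSES[k % len(VELOCITY_CLASSES)]
            speed = (
                profile.comfortable_speed
                * VELOCITY_FACTORS[vclass]
                * (1.0 + rng.normal(0.0, speed_jitter))
            )
            tpl = sample_template_params(rng)
            kfa = tpl["a1"] - tpl["a2"]
            load = synthesize_kjcf(
                profile, speed, kfa, model, rng.integers(2**31), n_samples=16
            )
            row = {
                "subject_id": profile.subject_id,
                "mass": profile.mass,
                "height": profile.height,
                "age": profile.age,
                "sex": profile.sex,
                "speed": speed,
                "kfa": kfa,
            }
            row.update(load.peaks_realized)
            rows.append(row)
    return pd.DataFrame(rows)
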