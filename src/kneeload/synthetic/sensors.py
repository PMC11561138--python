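"""Render IMU streams from planar trial kinematics.

Seven sensors (pelvis, both thighs, shanks, feet) report orientation as unit
quaternions and specific force in the sensor frame. Orientations come from
forward kinematics of the pelvis-thigh-shank-foot chain; accelerations from
twice-differentiated sensor positions plus gravity. Orientation noise is
modelled as a low-passed angular random process (soft-tissue-like wobble)
and accelerometer noise as white Gaussian noise.

World frame: X forward along the walking line, Y up, Z lateral; gravity is
-9.81 Y. Walking direction 'left' yaws the whole world by 180 degrees, as a
subject walking the opposite way past the camera would.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, filtfilt
from scipy.spatial.transform import Rotation

from ..timeseries import IMU_SITES, ImuStream
from .kinematics import TrialKinematics
from .noise import NOISE_NONE, NoiseProfile

GRAVITY = 9.81
#: Sensor position along its segment (fraction from proximal end).
_SENSOR_OFFSET = {"thigh": 0.5, "shank": 0.9}


def _lowpass_noise(rng: np.random.Generator, n: int, sd: float,
                   fs: float, cutoff: float = 5.0) -> np.ndarray:
    """(n, 3) correlated noise with per-axis SD ``sd`` after low-passing."""
    white = rng.normal(0.0, 1.0, size=(n, 3))
    if n > 30:
        b, a = butter(2, cutoff / (fs / 2.0), btype="low")
        white = filtfilt(b, a, white, axis=0)
        scale = np.std(white, axis=0)
        white = white / np.where(scale > 0, scale, 1.0)
    return white * sd


def render_imu(
    kin: TrialKinematics,
    noise: NoiseProfile = NOISE_NONE,
    seed: int | np.random.SeedSequence = 0,
) -> dict[str, ImuStream]:
    """Render the seven-sensor IMU bundle for one trial."""
    rng = np.random.default_rng(seed)
    n = len(kin.t)
    dt = 1.0 / kin.fs
    mirror = kin.direction == "left"

    # Per-site sagittal segment angle and world sensor position.
    site_angle: dict[str, np.ndarray] = {"pelvis": np.zeros(n)}
    site_pos: dict[str, np.ndarray] = {"pelvis": kin.hip}
    for leg, suffix in (("left", "l"), ("right", "r")):
        phi = kin.thigh_angle[leg]
        sig = kin.shank_angle[leg]
        thigh_dir = np.column_stack([np.sin(phi), -np.cos(phi)])
        shank_dir = np.column_stack([np.sin(sig), -np.cos(sig)])
        site_angle[f"thigh_{suffix}"] = phi
        site_pos[f"thigh_{suffix}"] = (
            kin.hip + _SENSOR_OFFSET["thigh"] * kin.thigh_len * thigh_dir
        )
        site_angle[f"shank_{suffix}"] = sig
        site_pos[f"shank_{suffix}"] = (
            kin.knee_pos[leg] + _SENSOR_OFFSET["shank"] * kin.shank_len * shank_dir
        )
        # Foot pitch follows the shank at reduced gain (flat-ish foot).
        psi = 0.3 * sig
        site_angle[f"foot_{suffix}"] = psi
        site_pos[f"foot_{suffix}"] = kin.ankle_pos[leg] + 0.10 * np.column_stack(
            [np.cos(psi), np.sin(psi)]
        )

    yaw = Rotation.from_euler("y", np.pi) if mirror else Rotation.identity()
    streams: dict[str, ImuStream] = {}
    for site in IMU_SITES:
        rot = yaw * Rotation.from_euler("z", site_angle[site][:, None])
        if noise.orientation_deg > 0:
            wobble = Rotation.from_rotvec(
                np.deg2rad(
                    _lowpass_noise(rng, n, noise.orientation_deg, kin.fs)
                )
            )
            rot = wobble * rot

        pos2 = site_pos[site]
        pos3 = np.column_stack([pos2[:, 0], pos2[:, 1], np.zeros(n)])
        if mirror:
            pos3[:, 0] *= -1.0
        vel = np.gradient(pos3, dt, axis=0)
        acc = np.gradient(vel, dt, axis=0)
        specific_world = acc + np.array([0.0, GRAVITY, 0.0])
        specific_sensor = rot.inv().apply(specific_world)
        if noise.accel_ms2 > 0:
            specific_sensor = specific_sensor + rng.normal(
                0.0, noise.accel_ms2, size=(n, 3)
            )

        quat = rot.as_quat(scalar_first=True)
        quat /= np.linalg.norm(quat, axis=1, keepdims=True)
        streams[site] = ImuStream(
            site=site, time=kin.t.copy(), quat=quat, accel=specific_sensor
        )
    return streams
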