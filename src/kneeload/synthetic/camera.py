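"""Render 2D pose-keypoint streams from planar trial kinematics.

A fixed virtual sagittal camera projects hips, knees, ankles and a head
landmark to pixel coordinates (image y points down). Optional pixel jitter
emulates pose-network noise; occlusion episodes around leg crossings lower
the far-side leg's confidence and bias its keypoints toward the near leg,
emulating how a single-camera pose estimate degrades when the analyzed leg
is hidden behind the other one. Keypoints outside the image are encoded as
missing, OpenPose-style, with the (0, 0, 0) triplet.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..timeseries import KeypointSeries
from .kinematics import TrialKinematics
from .noise import NOISE_NONE, NoiseProfile

#: Ankle-to-vertex height as a fraction of stature (anthropometric ratio).
BODY_EXTENT_RATIO = 0.936


@dataclass(frozen=True)
class CameraConfig:
    metres_per_pixel: float = 0.009
    image_size: tuple[int, int] = (480, 272)  # (width, height) px


def _project(world_xy: np.ndarray, x0: float, y0: float, mpp: float,
             size: tuple[int, int]) -> np.ndarray:
    """World (x forward, y up) -> pixel (u right, v down)."""
    u = (world_xy[:, 0] - x0) / mpp + size[0] / 2.0
    v = size[1] / 2.0 - (world_xy[:, 1] - y0) / mpp
    return np.column_stack([u, v])


def render_keypoints(
    kin: TrialKinematics,
    camera: CameraConfig | None = None,
    noise: NoiseProfile = NOISE_NONE,
    seed: int | np.random.SeedSequence = 0,
) -> KeypointSeries:
    """Project one trial's landmarks into the virtual camera."""
    cam = camera or CameraConfig()
    rng = np.random.default_rng(seed)
    n = len(kin.t)
    mirror = -1.0 if kin.direction == "left" else 1.0
    height_m = (kin.thigh_len + kin.shank_len) / (
        kin.config.thigh_fraction + kin.config.shank_fraction
    )

    def world(points: np.ndarray) -> np.ndarray:
        out = points.copy()
        out[:, 0] *= mirror
        return out

    # The head rides rigidly 0.936*height above the standing ankle level and
    # bobs with the pelvis, keeping head-to-ankle extent anthropometrically
    # consistent for scale calibration.
    ankle_standing_y = kin.hip[0, 1] - (kin.thigh_len + kin.shank_len)
    nose = np.column_stack([
        kin.hip[:, 0] + 0.03,
        BODY_EXTENT_RATIO * height_m + ankle_standing_y
        + (kin.hip[:, 1] - kin.hip[0, 1]),
    ])
    landmarks_world = {
        "Nose": world(nose),
        "MidHip": world(kin.hip),
        "RHip": world(kin.hip),
        "LHip": world(kin.hip),
        "RKnee": world(kin.knee_pos["right"]),
        "LKnee": world(kin.knee_pos["left"]),
        "RAnkle": world(kin.ankle_pos["right"]),
        "LAnkle": world(kin.ankle_pos["left"]),
    }

    # Camera centered on the walked path, mid-body height.
    x_mid = mirror * 0.5 * (kin.hip[0, 0] + kin.hip[-1, 0])
    y_mid = 0.5 * BODY_EXTENT_RATIO * height_m
    pix = {
        name: _project(w, x_mid, y_mid, cam.metres_per_pixel, cam.image_size)
        for name, w in landmarks_world.items()
    }

    conf = {
        name: rng.uniform(0.75, 0.95, size=n) for name in landmarks_world
    }

    # Occlusion: around each mid-swing of the near-side leg the far leg is
    # hidden; its keypoints lose confidence and drift toward the near leg.
    near = kin.direction  # 'right' walk -> right side faces the camera
    far = "left" if near == "right" else "right"
    far_prefix = "L" if far == "left" else "R"
    near_prefix = "R" if far == "left" else "L"
    for name in (f"{far_prefix}Hip", f"{far_prefix}Knee", f"{far_prefix}Ankle"):
        conf[name] *= 0.95
    if noise.occlusion:
        sf = kin.config.stance_fraction
        for h in kin.hs_times[near]:
            mid_swing = h + kin.gait_period * (sf + (1 - sf) * 0.5)
            half = 0.125 * kin.gait_period
            mask = np.abs(kin.t - mid_swing) <= half
            if not np.any(mask):
                continue
            for joint in ("Hip", "Knee", "Ankle"):
                fname, nname = f"{far_prefix}{joint}", f"{near_prefix}{joint}"
                conf[fname][mask] *= rng.uniform(0.15, 0.45)
                delta = pix[nname][mask] - pix[fname][mask]
                dist = np.linalg.norm(delta, axis=1, keepdims=True)
                unit = delta / np.where(dist > 1e-9, dist, 1.0)
                shift = np.minimum(dist, noise.occlusion_bias_px)
                pix[fname][mask] += unit * shift

    points: dict[str, np.ndarray] = {}
    w_px, h_px = cam.image_size
    for name in landmarks_world:
        p = pix[name]
        if noise.px_jitter > 0:
            p = p + rng.normal(0.0, noise.px_jitter, size=p.shape)
        c = np.clip(conf[name], 0.0, 1.0)
        visible = (
            (p[:, 0] >= 0) & (p[:, 0] < w_px) & (p[:, 1] >= 0) & (p[:, 1] < h_px)
        )
        arr = np.column_stack([p, c])
        arr[~visible] = 0.0  # OpenPose missing-detection convention
        points[name] = arr

    return KeypointSeries(
        points=points,
        fs=kin.fs,
        image_size=cam.image_size,
        extra={"metres_per_pixel": cam.metres_per_pixel,
               "direction": kin.direction},
    )
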