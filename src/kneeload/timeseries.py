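"""Per-trial time-series containers shared across the toolkit.

All signals are sampled uniformly at 100 Hz unless stated otherwise. Angles
are in degrees with knee flexion positive; forces in newtons; positions in
metres; image coordinates in pixels with the y axis pointing down.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

#: Canonical IMU sensor sites (pelvis + both thighs, shanks, feet).
IMU_SITES = ("pelvis", "thigh_l", "thigh_r", "shank_l", "shank_r", "foot_l", "foot_r")

#: OpenPose body-25 landmark order; landmarks we do not synthesize stay zeroed.
BODY25_NAMES = (
    "Nose", "Neck", "RShoulder", "RElbow", "RWrist", "LShoulder", "LElbow",
    "LWrist", "MidHip", "RHip", "RKnee", "RAnkle", "LHip", "LKnee", "LAnkle",
    "REye", "LEye", "REar", "LEar", "LBigToe", "LSmallToe", "LHeel",
    "RBigToe", "RSmallToe", "RHeel",
)
BODY25_INDEX = {name: i for i, name in enumerate(BODY25_NAMES)}


@dataclass
class FlexionCurve:
    """Knee flexion angle series (degrees, flexion positive) at uniform rate."""

    time: np.ndarray
    angle: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        if self.time.shape != self.angle.shape:
            raise InvalidArgumentError("time and angle must have equal length")
        if not np.all(np.isfinite(self.angle)):
            raise InvalidArgumentError("flexion angles must be finite")

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        if len(self.time) < 2:
            return float("nan")
        return 1.0 / float(np.median(np.diff(self.time)))

    def __len__(self) -> int:
        return len(self.time)


@dataclass(frozen=True)
class StanceWindow:
    """Half-open [start, end) index window of one stance phase."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise InvalidArgumentError(
                f"invalid stance window [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def slice(self) -> slice:
        return slice(self.start, self.end)


@dataclass
class KjcfCurvePair:
    """Medial and lateral compressive contact-force curves over one stance.

    The summed (medial + lateral) curve is derived pointwise on access.
    """

    medial: np.ndarray
    lateral: np.ndarray

    def __post_init__(self) -> None:
        self.medial = np.asarray(self.medial, dtype=float)
        self.lateral = np.asarray(self.lateral, dtype=float)
        if self.medial.shape != self.lateral.shape:
            raise InvalidArgumentError("medial/lateral curves must match in length")
        if np.any(self.medial < 0) or np.any(self.lateral < 0):
            raise InvalidArgumentError("contact forces must be non-negative")

    @property
    def summed(self) -> np.ndarray:
        return self.medial + self.lateral

    def __len__(self) -> int:
        return len(self.medial)


@dataclass
class ImuStream:
    """One sensor's orientation (unit quaternion, scalar-first wxyz) and
    specific-force acceleration (m/s^2, sensor frame) at 100 Hz."""

    site: str
    time: np.ndarray
    quat: np.ndarray
    accel: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.quat = np.asarray(self.quat, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        n = len(self.time)
        if self.quat.shape != (n, 4) or self.accel.shape != (n, 3):
            raise InvalidArgumentError("quat must be (n,4), accel (n,3)")
        norms = np.linalg.norm(self.quat, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise InvalidArgumentError("orientation quaternions must be unit norm")

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class KeypointSeries:
    """Per-frame 2D pose keypoints (pixel x, pixel y, confidence).

    ``points`` maps a body-25 landmark name to an (n_frames, 3) array. A
    missing detection is encoded OpenPose-style as the (0, 0, 0) triplet.
    """

    points: dict[str, np.ndarray]
    fs: float
    image_size: tuple[int, int] = (480, 272)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.n_frames
        for name, arr in self.points.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (n, 3):
                raise InvalidArgumentError(f"landmark {name} must be (n,3)")
            if np.any((arr[:, 2] < 0) | (arr[:, 2] > 1)):
                raise InvalidArgumentError("confidences must lie in [0,1]")
            self.points[name] = arr

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.points.values())))

    def landmark(self, name: str) -> np.ndarray:
        return self.points[name]

    def leg_landmarks(self, leg: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(hip, knee, ankle) arrays for ``leg`` in {'left', 'right'}."""
        side = "L" if leg == "left" else "R"
        return (
            self.points[f"{side}Hip"],
            self.points[f"{side}Knee"],
            self.points[f"{side}Ankle"],
        )
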