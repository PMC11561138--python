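"""Walking speed and knee flexion angle from IMU orientation + acceleration.

Speed: heel strikes are detected from the shank acceleration magnitude; the
thighs and shanks are treated as rigid bodies (lengths as height fractions)
hanging from a common proximal point, so sensor orientations give each
foot's position relative to the pelvis. Assuming the supporting foot is
stationary on the ground between detected heel strikes lets the pelvis
trajectory be dead-reckoned, and stride length is the displacement of a
foot between its consecutive heel strikes; speed = stride length / gait
period.

Flexion: per sensor, orientations are expressed as rotation vectors
relative to the neutral first frame; the first principal axis of those
rotation vectors is the dominant (flexion) axis, and the knee flexion angle
is the difference between the shank's and the thigh's signed rotation about
it, sign-fixed so that flexion is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks
from scipy.spatial.transform import Rotation

from .errors import (
    InsufficientCyclesError,
    InvalidArgumentError,
    MissingStreamError,
)
from .gait_features import compute_kfa_predictor
from .timeseries import FlexionCurve, ImuStream, StanceWindow


@dataclass(frozen=True)
class SegmentChainConfig:
    """Thigh/shank lengths as fractions of stature (standard anthropometric
    table values by default)."""

    thigh_fraction: float = 0.245
    shank_fraction: float = 0.246
    stance_fraction: float = 0.62  # stance share of the gait cycle

    def __post_init__(self) -> None:
        for f in (self.thigh_fraction, self.shank_fraction):
            if not 0.0 < f < 0.5:
                raise InvalidArgumentError("segment fractions must be in (0, 0.5)")


@dataclass
class GaitCycleEvents:
    """Heel-strike sample indices for one leg plus the median gait period."""

    indices: np.ndarray
    gait_period: float  # s

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if np.any(np.diff(self.indices) <= 0):
            raise InvalidArgumentError("event indices must be strictly increasing")
        if self.gait_period <= 0:
            raise InvalidArgumentError("gait period must be positive")


def detect_gait_cycles(
    shank_accel: ImuStream,
    lowpass_hz: float = 10.0,
    min_separation_s: float = 0.5,
    prominence_factor: float = 0.5,
) -> GaitCycleEvents:
    """Heel strikes from the low-passed shank acceleration magnitude.

    Peaks must be separated by at least ``min_separation_s`` and have a
    prominence of at least ``prominence_factor`` times the filtered signal's
    standard deviation. The gait period is the median inter-event interval.
    """
    fs = shank_accel.fs
    if len(shank_accel) < 2 * fs:
        raise InsufficientCyclesError("need at least 2 s of data")
    mag = np.linalg.norm(shank_accel.accel, axis=1)
    b, a = butter(4, lowpass_hz / (fs / 2.0), btype="low")
    filt = filtfilt(b, a, mag)
    sd = float(np.std(filt))
    if sd < 1e-9:
        raise InsufficientCyclesError("acceleration carries no gait signal")
    peaks, _ = find_peaks(
        filt,
        distance=max(1, int(round(min_separation_s * fs))),
        prominence=prominence_factor * sd,
    )
    if len(peaks) < 2:
        raise InsufficientCyclesError(f"only {len(peaks)} gait event(s) found")
    period = float(np.median(np.diff(peaks)) / fs)
    return GaitCycleEvents(indices=peaks, gait_period=period)


def _require(streams: dict, site: str) -> ImuStream:
    try:
        return streams[site]
    except KeyError:
        raise MissingStreamError(site) from None


def _relative_foot_positions(
    streams: dict, height: float, chain: SegmentChainConfig
) -> dict[str, np.ndarray]:
    """Distal shank endpoint of each leg relative to the common proximal
    point, from sensor orientations (3D, metres)."""
    height_m = height / 100.0
    lt = chain.thigh_fraction * height_m
    ls = chain.shank_fraction * height_m
    down = np.array([0.0, -1.0, 0.0])
    rel = {}
    for leg, suffix in (("left", "l"), ("right", "r")):
        thigh = _require(streams, f"thigh_{suffix}")
        shank = _require(streams, f"shank_{suffix}")
        r_t = Rotation.from_quat(thigh.quat, scalar_first=True)
        r_s = Rotation.from_quat(shank.quat, scalar_first=True)
        rel[leg] = r_t.apply(lt * down) + r_s.apply(ls * down)
    return rel


def estimate_walking_speed_imu(
    streams: dict,
    height: float,
    chain: SegmentChainConfig | None = None,
    events: dict[str, GaitCycleEvents] | None = None,
    max_period_deviation: float = 0.35,
) -> float:
    """Walking speed (cm/s) from thigh + shank orientations and heel strikes.

    ``events`` maps 'left'/'right' to that leg's detected heel strikes; when
    omitted they are detected from the shank accelerations. Strides whose
    duration deviates more than ``max_period_deviation`` (fractional) from
    the median are discarded as lead-in/edge artifacts.
    """
    chain = chain or SegmentChainConfig()
    if events is None:
        events = {
            "left": detect_gait_cycles(_require(streams, "shank_l")),
            "right": detect_gait_cycles(_require(streams, "shank_r")),
        }
    rel = _relative_foot_positions(streams, height, chain)
    fs = _require(streams, "shank_r").fs
    n = len(rel["left"])

    period = float(np.mean([events[leg].gait_period for leg in ("left", "right")]))
    # Hand the pelvis over to the newly struck foot a few samples after each
    # detected strike, i.e. inside the double-support interval when both
    # feet are on the ground; this tolerates event-timing error.
    sw = int(round(0.06 * period * fs))
    switches = sorted(
        (int(i) + sw, leg)
        for leg in ("left", "right")
        for i in events[leg].indices
        if 0 <= int(i) + sw < n
    )
    if len(switches) < 3:
        raise InsufficientCyclesError("too few anchored stances")

    # Dead-reckon the pelvis by pinning the most recently planted foot.
    pelvis = np.zeros((n, 3))
    s0, leg0 = switches[0]
    anchor = rel[leg0][s0].copy()
    pelvis[: s0 + 1] = anchor - rel[leg0][: s0 + 1]
    for (s_a, leg_a), (s_b, leg_b) in zip(switches, switches[1:] + [(n - 1, None)]):
        pelvis[s_a : s_b + 1] = anchor - rel[leg_a][s_a : s_b + 1]
        if leg_b is not None:
            anchor = pelvis[s_b] + rel[leg_b][s_b]

    # Stride lengths: displacement of each foot between consecutive strikes,
    # sampled at mid-stance when the foot is reliably flat on the ground;
    # speed averages stride length / stride duration over retained strides.
    mid = int(round(0.25 * period * fs))
    ratios = []
    for leg in ("left", "right"):
        idxs = np.array([int(i) + mid for i in events[leg].indices
                         if int(i) + mid < n])
        if len(idxs) < 2:
            continue
        periods = np.diff(idxs) / fs
        med = np.median(periods)
        foot_world = pelvis[idxs] + rel[leg][idxs]
        strides = np.linalg.norm(np.diff(foot_world, axis=0), axis=1)
        keep = np.abs(periods - med) <= max_period_deviation * med
        ratios.extend(strides[keep] / periods[keep])
    if not ratios:
        raise InsufficientCyclesError("no usable strides")
    return float(np.mean(ratios) * 100.0)


def _principal_rotation(rotvecs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(axis, signed angles deg) for the dominant rotation axis of a set of
    frame-0-relative rotation vectors."""
    centered = rotvecs - rotvecs.mean(axis=0)
    if np.linalg.norm(centered) < 1e-10:
        return np.zeros(3), np.zeros(len(rotvecs))
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    return axis, np.rad2deg(rotvecs @ axis)


def estimate_kfa_series_imu(
    thigh: ImuStream, shank: ImuStream
) -> FlexionCurve:
    """Knee flexion angle series from thigh and shank IMU orientations.

    The first frame (neutral standing) defines zero; the sign is fixed so
    that flexion — which dominates the swing phase — is positive on average.
    A motionless sensor contributes a flat zero rotation.
    """
    rt = Rotation.from_quat(thigh.quat, scalar_first=True)
    rs = Rotation.from_quat(shank.quat, scalar_first=True)
    v_t = (rt[0].inv() * rt).as_rotvec()
    v_s = (rs[0].inv() * rs).as_rotvec()
    ax_t, ang_t = _principal_rotation(v_t)
    ax_s, ang_s = _principal_rotation(v_s)
    # Degenerate (motionless) sensors borrow the other sensor's axis.
    if np.linalg.norm(ax_t) == 0 and np.linalg.norm(ax_s) > 0:
        ang_t = np.rad2deg(v_t @ ax_s)
    if np.linalg.norm(ax_s) == 0 and np.linalg.norm(ax_t) > 0:
        ang_s = np.rad2deg(v_s @ ax_t)
    if np.dot(ax_t, ax_s) < 0:
        ang_s = -ang_s
    kfa = ang_s - ang_t
    kfa -= kfa[0]
    if np.mean(kfa) < 0:
        kfa = -kfa
    return FlexionCurve(time=thigh.time.copy(), angle=kfa)


def estimate_kfa_predictor_imu(
    streams: dict,
    leg: str = "right",
    chain: SegmentChainConfig | None = None,
    events: GaitCycleEvents | None = None,
) -> float:
    """KFA predictor (degrees) for one leg, averaged over interior stances.

    Without a force plate, each stance window is taken as heel strike to
    heel strike + stance_fraction x gait period.
    """
    chain = chain or SegmentChainConfig()
    suffix = "l" if leg == "left" else "r"
    shank = _require(streams, f"shank_{suffix}")
    thigh = _require(streams, f"thigh_{suffix}")
    if events is None:
        events = detect_gait_cycles(shank)
    curve = estimate_kfa_series_imu(thigh, shank)
    fs = shank.fs
    ns = int(round(chain.stance_fraction * events.gait_period * fs))
    idxs = events.indices
    interior = idxs[1:-1] if len(idxs) > 3 else idxs[:-1]
    values = []
    for i in interior:
        if i + ns <= len(curve):
            values.append(
                compute_kfa_predictor(curve, StanceWindow(int(i), int(i) + ns))
            )
    if not values:
        raise InsufficientCyclesError("no complete stance window in trial")
    return float(np.mean(values))
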