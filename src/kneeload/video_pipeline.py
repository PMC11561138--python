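"""Walking speed and knee flexion angle from 2D sagittal pose keypoints.

Scale: the pixel extent from the head landmark down to the ankles, compared
with the subject's stature (ankle-to-vertex is about 0.936 x height), gives
metres per pixel. Speed: the absolute slope of a robust (least absolute
deviations) straight-line fit of the hip keypoint's horizontal pixel
position against time. Flexion: 180 degrees minus the included angle of the
(knee->hip, knee->ankle) vectors; low-confidence frames are interpolated so
the series stays uniformly sampled. All quantities are computed from vector
geometry, so they are invariant to mirroring and to uniform scaling or
translation of the pixel coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.signal import savgol_filter

from .errors import (
    CalibrationError,
    InsufficientDataError,
    InvalidArgumentError,
    LowQualityError,
    NoStanceError,
)
from .gait_features import compute_kfa_predictor, segment_stance
from .timeseries import FlexionCurve, KeypointSeries, StanceWindow

#: Ankle-to-vertex height as a fraction of stature.
BODY_EXTENT_RATIO = 0.936


@dataclass(frozen=True)
class CameraScale:
    metres_per_pixel: float

    def __post_init__(self) -> None:
        if self.metres_per_pixel <= 0:
            raise InvalidArgumentError("metres_per_pixel must be positive")


def estimate_scale(
    series: KeypointSeries,
    height: float,
    min_confidence: float = 0.5,
    override: float | None = None,
) -> CameraScale:
    """Pixel-to-metre scale from full-body pixel extent vs subject stature.

    Frames need confident head, hip and ankle detections with the hip inside
    the central 40% of the image; the 95th-percentile extent over those
    frames approximates the standing (tallest) pose. An explicit ``override``
    (m/px) bypasses the estimate.
    """
    if override is not None:
        return CameraScale(metres_per_pixel=override)
    head = series.landmark("Nose")
    hip = series.landmark("MidHip")
    r_ankle = series.landmark("RAnkle")
    l_ankle = series.landmark("LAnkle")
    w_px = series.image_size[0]
    ok = (
        (head[:, 2] >= min_confidence)
        & (hip[:, 2] >= min_confidence)
        & (r_ankle[:, 2] >= min_confidence)
        & (l_ankle[:, 2] >= min_confidence)
        & (np.abs(hip[:, 0] - w_px / 2.0) <= 0.2 * w_px)
    )
    if not np.any(ok):
        raise CalibrationError("no high-confidence full-body frame near centre")
    extent = np.maximum(r_ankle[ok, 1], l_ankle[ok, 1]) - head[ok, 1]
    extent = extent[extent > 0]
    if len(extent) == 0:
        raise CalibrationError("degenerate body extent")
    px = float(np.percentile(extent, 95))
    return CameraScale(metres_per_pixel=BODY_EXTENT_RATIO * (height / 100.0) / px)


def estimate_walking_speed_vc(
    series: KeypointSeries,
    scale: CameraScale,
    min_confidence: float = 0.3,
) -> float:
    """Walking speed (cm/s) from the hip keypoint's horizontal drift.

    A least-absolute-deviations line is fitted to hip x vs time over the
    accepted frames; the fit tolerates dropouts and occlusion outliers. The
    absolute slope makes the estimate direction-agnostic.
    """
    hip = series.landmark("MidHip")
    ok = hip[:, 2] >= min_confidence
    if int(ok.sum()) < 10:
        raise InsufficientDataError("fewer than 10 confident hip frames")
    t = np.flatnonzero(ok) / series.fs
    x = hip[ok, 0]
    exog = sm.add_constant(t)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # median regression may stop at max_iter
        fit = sm.QuantReg(x, exog).fit(q=0.5)
    slope_px_s = float(fit.params[1])
    return abs(slope_px_s) * scale.metres_per_pixel * 100.0


def estimate_kfa_series_vc(
    series: KeypointSeries,
    leg: str = "right",
    min_confidence: float = 0.3,
    smooth_window: int = 11,
) -> FlexionCurve:
    """Knee flexion series from hip/knee/ankle keypoints of one leg.

    Flexion = 180 deg - included angle at the knee. Frames where any of the
    three landmarks falls below ``min_confidence`` are linearly interpolated
    from their neighbours; a light Savitzky-Golay smoother (disabled with
    ``smooth_window=0``) suppresses pose-network jitter.
    """
    hip, knee, ankle = series.leg_landmarks(leg)
    conf = np.minimum(np.minimum(hip[:, 2], knee[:, 2]), ankle[:, 2])
    ok = conf >= min_confidence
    n = len(conf)
    i0, i1 = _visible_range(series, min_confidence)
    if ok[i0:i1].sum() <= (i1 - i0) / 2:
        raise LowQualityError("more than half of the tracked frames are unreliable")
    if not np.any(ok):
        raise LowQualityError("no reliable frame")
    v1 = hip[:, :2] - knee[:, :2]
    v2 = ankle[:, :2] - knee[:, :2]
    cosang = np.einsum("ij,ij->i", v1, v2) / (
        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1) + 1e-12
    )
    flexion = 180.0 - np.rad2deg(np.arccos(np.clip(cosang, -1.0, 1.0)))
    idx = np.arange(n)
    flexion = np.interp(idx, idx[ok], flexion[ok])
    if smooth_window and n > smooth_window:
        flexion = savgol_filter(flexion, smooth_window, polyorder=3)
    return FlexionCurve(time=idx / series.fs, angle=flexion)


def _visible_range(series: KeypointSeries, min_confidence: float) -> tuple[int, int]:
    """Frame span [i0, i1) during which the subject is tracked (the fixed
    camera sees only part of the walkway)."""
    hip = series.landmark("MidHip")
    ok = np.flatnonzero(hip[:, 2] >= min_confidence)
    if len(ok) == 0:
        raise InsufficientDataError("subject never confidently visible")
    return int(ok[0]), int(ok[-1]) + 1


def detect_stance_windows_vc(
    series: KeypointSeries,
    leg: str = "right",
    min_confidence: float = 0.3,
    speed_fraction: float = 0.25,
) -> list[StanceWindow]:
    """Stance windows from ankle stationarity in the image.

    The supporting foot is still while the body passes over it, so frames
    where the smoothed ankle pixel speed drops below ``speed_fraction`` of
    its 90th percentile form ground-contact runs; each sufficiently long run
    is one stance.
    """
    _, _, ankle = series.leg_landmarks(leg)
    ok = ankle[:, 2] >= min_confidence
    n = len(ok)
    idx = np.arange(n)
    if ok.sum() < 10:
        raise InsufficientDataError("too few confident ankle frames")
    xy = np.column_stack(
        [np.interp(idx, idx[ok], ankle[ok, 0]), np.interp(idx, idx[ok], ankle[ok, 1])]
    )
    # Differentiate smoothed positions: raw keypoint jitter would otherwise
    # swamp the near-zero stance velocity.
    if n > 15:
        xy = savgol_filter(xy, 15, polyorder=3, axis=0)
    vel = np.linalg.norm(np.gradient(xy, axis=0), axis=1) * series.fs
    if n > 11:
        vel = savgol_filter(vel, 11, polyorder=2)
    i0, i1 = _visible_range(series, min_confidence)
    vis = vel[i0:i1]
    thr = speed_fraction * float(np.percentile(vis, 90))
    contact = vel < thr
    contact[: i0 + 2] = False
    contact[max(i1 - 2, 0):] = False
    # Split contact into contiguous runs; keep gait-plausible ones.
    windows: list[StanceWindow] = []
    start = None
    for i in range(n + 1):
        inside = i < n and contact[i]
        if inside and start is None:
            start = i
        elif not inside and start is not None:
            if i - start >= 0.25 * series.fs:  # >= 0.25 s of ground contact
                windows.append(StanceWindow(start, i))
            start = None
    if not windows:
        raise NoStanceError("no ankle-stationary interval found")
    return windows


def estimate_kfa_predictor_vc(
    series: KeypointSeries,
    leg: str = "right",
    min_confidence: float = 0.3,
) -> float:
    """KFA predictor (degrees) from video keypoints, averaged over the
    detected stance windows (edge windows are dropped when enough remain)."""
    curve = estimate_kfa_series_vc(series, leg=leg, min_confidence=min_confidence)
    windows = detect_stance_windows_vc(series, leg=leg, min_confidence=min_confidence)
    if len(windows) > 3:
        windows = windows[1:-1]
    durations = np.array([len(w) for w in windows])
    med = np.median(durations)
    values = [
        compute_kfa_predictor(curve, w)
        for w, d in zip(windows, durations)
        if 0.6 * med <= d <= 1.5 * med and len(w) >= 4
    ]
    if not values:
        raise InsufficientDataError("no usable stance window")
    return float(np.mean(values))
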