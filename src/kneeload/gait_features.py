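"""Scalar gait features: the knee-flexion-angle predictor, the nine
stance-phase loading peaks, stance segmentation, and strength scaling.

The nine response variables are {loading response, terminal extension,
full-stance max} x {summed, medial, lateral} compressive tibiofemoral
contact force. The loading response (LR) is the first peak of the stance
loading curve, terminal extension (TE) the second; the full-stance maximum
always equals the higher of the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .errors import InvalidArgumentError, NoStanceError
from .timeseries import FlexionCurve, KjcfCurvePair, StanceWindow

COMPARTMENTS = ("summed", "medial", "lateral")
PEAK_TYPES = ("lr", "te", "max")
#: The nine response variables, in canonical order.
RESPONSE_VARIABLES = tuple(
    f"{peak}_{comp}" for comp in COMPARTMENTS for peak in PEAK_TYPES
)

#: Window (samples) of the moving average applied before local-maximum
#: detection. Raw curve values are reported at the detected indices.
PEAK_SMOOTHING_WINDOW = 5


@dataclass
class LoadingPeakSet:
    """The nine stance-phase loading peaks (newtons).

    ``values`` is keyed by :data:`RESPONSE_VARIABLES` names such as
    ``"lr_medial"`` or ``"max_summed"``. ``degenerate`` flags an all-zero
    input curve.
    """

    values: dict[str, float]
    degenerate: bool = False

    def __post_init__(self) -> None:
        missing = set(RESPONSE_VARIABLES) - set(self.values)
        if missing:
            raise InvalidArgumentError(f"missing peaks: {sorted(missing)}")
        for name, v in self.values.items():
            if v < 0:
                raise InvalidArgumentError(f"negative peak {name}={v}")

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def as_dict(self) -> dict[str, float]:
        return dict(self.values)


def compute_kfa_predictor(curve: FlexionCurve, stance: StanceWindow) -> float:
    """Knee-flexion-angle predictor in degrees.

    The scalar predictor is the maximum flexion over the first half of the
    stance phase minus the minimum over the second half. The half boundary is
    ``start + floor(len/2)``; the first half is closed-left/open-right.
    """
    if len(stance) < 4:
        raise InvalidArgumentError("stance window must span >= 4 samples")
    if stance.end > len(curve):
        raise InvalidArgumentError("stance window exceeds curve length")
    angle = curve.angle[stance.slice()]
    mid = len(angle) // 2
    return float(np.max(angle[:mid]) - np.min(angle[mid:]))


def _half_peak(raw: np.ndarray, smooth: np.ndarray, lo: int, hi: int) -> float:
    """Largest interior local maximum of ``smooth`` restricted to
    [lo, hi), reported as the raw value at that index; falls back to the raw
    maximum over the window when no interior local maximum exists."""
    interior = np.arange(max(lo, 1), min(hi, len(smooth) - 1))
    is_max = (smooth[interior] > smooth[interior - 1]) & (
        smooth[interior] > smooth[interior + 1]
    )
    candidates = interior[is_max]
    if len(candidates) == 0:
        return float(np.max(raw[lo:hi]))
    best = candidates[np.argmax(smooth[candidates])]
    return float(raw[best])


def extract_loading_peaks(curves: KjcfCurvePair) -> LoadingPeakSet:
    """Extract the nine loading peaks from one stance's compartmental curves.

    For each of the summed, medial, and lateral curves, LR is the largest
    local maximum in the first half of stance and TE in the second half
    (local maxima are found on a 5-sample moving average; raw values are
    reported). When a half contains no interior local maximum — lateral
    curves can lack the double-bump shape — the plain maximum over that half
    is used instead. The full-stance max is max(LR, TE) by construction.
    """
    n = len(curves)
    if n < 4:
        raise InvalidArgumentError("curves must span >= 4 samples")
    series = {
        "summed": curves.summed,
        "medial": curves.medial,
        "lateral": curves.lateral,
    }
    degenerate = bool(np.all(curves.summed == 0))
    mid = n // 2
    values: dict[str, float] = {}
    for comp, raw in series.items():
        smooth = uniform_filter1d(raw, size=PEAK_SMOOTHING_WINDOW, mode="nearest")
        lr = _half_peak(raw, smooth, 0, mid)
        te = _half_peak(raw, smooth, mid, n)
        values[f"lr_{comp}"] = lr
        values[f"te_{comp}"] = te
        values[f"max_{comp}"] = max(lr, te)
    return LoadingPeakSet(values=values, degenerate=degenerate)


def scale_max_isometric_force(subject_mass: float, generic_mass: float) -> float:
    """Maximum-isometric-force scale factor 1.5 * (mass ratio)^(2/3).

    The 2/3 exponent assumes an allometric relationship between body mass and
    muscle cross-sectional area; the 1.5 headroom factor prevents saturated
    muscle activations at the fastest walking speeds.
    """
    if subject_mass <= 0 or generic_mass <= 0:
        raise InvalidArgumentError("masses must be positive")
    return 1.5 * (subject_mass / generic_mass) ** (2.0 / 3.0)


def segment_stance(series: np.ndarray, threshold: float = 20.0) -> StanceWindow:
    """Longest contiguous suprathreshold run of a vertical-force series, or
    of boolean contact flags, as a half-open stance window."""
    series = np.asarray(series)
    contact = series if series.dtype == bool else series > threshold
    if not np.any(contact):
        raise NoStanceError("no suprathreshold interval found")
    padded = np.concatenate([[False], contact, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, ends = edges[::2], edges[1::2]
    best = np.argmax(ends - starts)
    return StanceWindow(int(starts[best]), int(ends[best]))
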