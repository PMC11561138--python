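"""Planar (sagittal) gait kinematics with analytic ground truth.

The model prescribes, per trial, a stance knee-flexion template (early-stance
flexion bump, late-stance extension minimum) and a hip that advances at
constant walking speed with a small periodic oscillation. During each stance
the ankle of the supporting leg is pinned at a fixed ground anchor: the thigh
angle is solved in closed form from the two-link chain so that the ankle's
horizontal position stays exactly on the anchor. Swing phases interpolate the
thigh angle between consecutive stance solutions and carry a >= 60 degree
flexion bump. The trial opens with a short neutral standing interval, which
downstream estimators use as the zero-orientation reference.

Everything is driven by one seed, so trials are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..errors import InvalidArgumentError
from ..timeseries import FlexionCurve, StanceWindow
from .cohort import SubjectProfile

VELOCITY_FACTORS = {"slow": 0.75, "comfortable": 1.0, "fast": 1.25}
LEGS = ("left", "right")


@dataclass(frozen=True)
class KinematicsConfig:
    """Tunables of the planar gait generator.

    Segment lengths follow standard anthropometric height fractions; the
    stance phase occupies 62% of the gait cycle (typical level walking).
    """

    fs: float = 100.0
    thigh_fraction: float = 0.245
    shank_fraction: float = 0.246
    stance_fraction: float = 0.62
    n_strides: int = 6
    stand_duration: float = 0.5  # s of neutral standing at trial start
    lead_in: float = 0.30  # s blend from standing into the first stance
    gait_period: float | None = None  # s; None -> speed-dependent default
    hip_speed_osc: float = 0.010  # m amplitude of horizontal oscillation
    hip_vert_osc: float = 0.012  # m amplitude of vertical oscillation


@dataclass
class TrialKinematics:
    """Full ground-truth kinematic state of one simulated walking trial."""

    t: np.ndarray
    fs: float
    direction: str  # 'left' or 'right' (walking direction w.r.t. the camera)
    true_speed: float  # cm/s
    gait_period: float  # s
    thigh_len: float  # m
    shank_len: float  # m
    hip: np.ndarray  # (n, 2) world (x forward, y up), metres
    thigh_angle: dict[str, np.ndarray]  # radians from vertical, + forward
    shank_angle: dict[str, np.ndarray]
    knee_pos: dict[str, np.ndarray]  # (n, 2) m
    ankle_pos: dict[str, np.ndarray]  # (n, 2) m
    flexion_deg: dict[str, np.ndarray]
    hs_times: dict[str, np.ndarray]  # heel-strike times, s
    stance_windows: dict[str, list[StanceWindow]]  # full stances only
    template: dict  # sampled template parameters (degrees)
    analyzed_leg: str = "right"
    config: KinematicsConfig = field(default_factory=KinematicsConfig)

    @property
    def kfa_predictor_truth(self) -> float:
        """Early-stance flexion peak minus late-stance minimum, degrees."""
        return self.template["a1"] - self.template["a2"]

    @property
    def stance_truth(self) -> StanceWindow:
        """A representative (middle) stance window of the analyzed leg."""
        windows = self.stance_windows[self.analyzed_leg]
        return windows[len(windows) // 2]

    def flexion_truth(self, leg: str | None = None) -> FlexionCurve:
        leg = leg or self.analyzed_leg
        return FlexionCurve(time=self.t, angle=self.flexion_deg[leg])


def _cos_interp(u: np.ndarray, ya: float, yb: float) -> np.ndarray:
    return ya + (yb - ya) * 0.5 * (1.0 - np.cos(np.pi * u))


def _stance_template(ns: int, a1: float, a2: float,
                     k_hs: float, k_to: float) -> np.ndarray:
    """Double-bump stance flexion on ``ns`` samples.

    Breakpoints are snapped to the sample grid so the sampled maximum of the
    first half equals ``a1`` and the sampled minimum of the second half
    equals ``a2`` exactly.
    """
    p = np.linspace(0.0, 1.0, ns)
    p1 = round(0.25 * (ns - 1)) / (ns - 1)
    p2 = round(0.78 * (ns - 1)) / (ns - 1)
    k = np.empty(ns)
    seg1 = p <= p1
    seg2 = (p > p1) & (p <= p2)
    seg3 = p > p2
    k[seg1] = _cos_interp(p[seg1] / p1, k_hs, a1)
    k[seg2] = _cos_interp((p[seg2] - p1) / (p2 - p1), a1, a2)
    k[seg3] = _cos_interp((p[seg3] - p2) / (1.0 - p2), a2, k_to)
    return k


def _swing_template(u: np.ndarray, k_to: float, k_sw: float,
                    k_hs: float) -> np.ndarray:
    """Swing flexion: rise to the swing peak at 45% swing, then extend."""
    k = np.empty_like(u)
    up = u <= 0.45
    k[up] = _cos_interp(u[up] / 0.45, k_to, k_sw)
    k[~up] = _cos_interp((u[~up] - 0.45) / 0.55, k_sw, k_hs)
    return k


def _closure_phi(c: np.ndarray, k_deg: np.ndarray,
                 lt: float, ls: float) -> np.ndarray:
    """Thigh angle placing the ankle at horizontal offset ``c`` from the hip,
    given knee flexion ``k`` (degrees). Closed form for the two-link chain."""
    k = np.deg2rad(k_deg)
    r = np.hypot(lt + ls * np.cos(k), ls * np.sin(k))
    delta = np.arctan2(ls * np.sin(k), lt + ls * np.cos(k))
    return delta + np.arcsin(np.clip(c / r, -0.999, 0.999))


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def sample_template_params(rng: np.random.Generator) -> dict[str, float]:
    """Draw one trial's stance/swing flexion template (degrees).

    ``a1`` is the early-stance flexion peak, ``a2`` the late-stance minimum
    (the KFA predictor ground truth is a1 - a2), ``k_hs``/``k_to`` the
    heel-strike and toe-off flexion, ``k_sw`` the swing peak.
    """
    a2 = float(rng.uniform(0.0, 8.0))
    return {
        "a1": float(rng.uniform(10.0, 25.0)),
        "a2": a2,
        "k_hs": float(rng.uniform(2.0, 6.0)),
        "k_to": a2 + float(rng.uniform(1.5, 4.0)),
        "k_sw": float(rng.uniform(58.0, 68.0)),
    }


def synthesize_kinematics(
    profile: SubjectProfile,
    velocity_class: str,
    direction: str,
    seed: int | np.random.SeedSequence,
    config: KinematicsConfig | None = None,
) -> TrialKinematics:
    """Generate one trial's planar kinematics with full ground truth.

    ``velocity_class`` scales the subject's comfortable speed by 0.75 / 1.0 /
    1.25 for slow / comfortable / fast. ``direction`` only tags which way the
    subject walks past the (virtual) camera; the kinematics are canonical.
    """
    if velocity_class not in VELOCITY_FACTORS:
        raise InvalidArgumentError(f"unknown velocity class {velocity_class!r}")
    if direction not in LEGS:
        raise InvalidArgumentError(f"direction must be 'left' or 'right'")
    cfg = config or KinematicsConfig()
    rng = np.random.default_rng(seed)

    v_cms = profile.comfortable_speed * VELOCITY_FACTORS[velocity_class]
    v = v_cms / 100.0
    height_m = profile.height / 100.0
    lt = cfg.thigh_fraction * height_m
    ls = cfg.shank_fraction * height_m

    period = cfg.gait_period
    if period is None:
        period = 1.05 * (1.34 / v) ** 0.42 * (1.0 + rng.uniform(-0.03, 0.03))
    period = float(np.clip(period, 0.7, 1.6))
    stance_len = cfg.stance_fraction * period

    # Stance/swing flexion template parameters (degrees).
    tpl = sample_template_params(rng)
    a1, a2 = tpl["a1"], tpl["a2"]
    k_hs, k_to, k_sw = tpl["k_hs"], tpl["k_to"], tpl["k_sw"]

    t_walk = cfg.stand_duration
    first_hs = t_walk + cfg.lead_in
    hs = {
        "right": first_hs + period * np.arange(cfg.n_strides + 1),
        "left": first_hs + period / 2.0 + period * np.arange(cfg.n_strides),
    }
    t_end = hs["right"][-1] + 0.45 * period
    n = int(round(t_end * cfg.fs)) + 1
    t = np.arange(n) / cfg.fs

    # Hip trajectory: speed ramps up over the lead-in, then small periodic
    # oscillations around the constant-speed advance.
    ramp = _smoothstep((t - t_walk) / max(cfg.lead_in, 1e-6))
    speed_series = v * ramp * (
        1.0 + cfg.hip_speed_osc * np.sin(4.0 * np.pi * (t - t_walk) / period)
    )
    x = np.concatenate([[0.0], np.cumsum(0.5 * (speed_series[1:] + speed_series[:-1]) / cfg.fs)])
    h0 = 0.96 * (lt + ls)
    y = h0 + cfg.hip_vert_osc * ramp * 0.5 * (
        np.cos(4.0 * np.pi * (t - t_walk) / period) - 1.0
    )
    hip = np.column_stack([x, y])

    def xf(time: float) -> float:
        """Hip x at an arbitrary time (linear extrapolation past trial end)."""
        if time <= t[-1]:
            return float(np.interp(time, t, x))
        return float(x[-1] + v * (time - t[-1]))

    ns = int(round(stance_len * cfg.fs))
    template = _stance_template(ns, a1, a2, k_hs, k_to)

    phi = {leg: np.zeros(n) for leg in LEGS}
    k = {leg: np.zeros(n) for leg in LEGS}
    stance_windows: dict[str, list[StanceWindow]] = {leg: [] for leg in LEGS}

    for leg in LEGS:
        events = hs[leg]
        seg_bounds = []  # (i0, i1, phi_at_hs, phi_at_to) per stance
        for h in events:
            se = h + stance_len
            i0 = int(math.ceil(h * cfg.fs))
            i1 = min(i0 + ns, n)
            anchor = xf(h) + 0.5 * (xf(se) - xf(h))
            idx = np.arange(i0, i1)
            k[leg][idx] = template[: i1 - i0]
            phi[leg][idx] = _closure_phi(anchor - x[idx], k[leg][idx], lt, ls)
            phi_hs = float(_closure_phi(np.array([anchor - xf(h)]),
                                        np.array([k_hs]), lt, ls)[0])
            phi_to = float(_closure_phi(np.array([anchor - xf(se)]),
                                        np.array([k_to]), lt, ls)[0])
            seg_bounds.append((i0, i1, phi_hs, phi_to))
            if i1 - i0 == ns:
                stance_windows[leg].append(StanceWindow(i0, i0 + ns))

        # Swing between consecutive stances (the last one may end off-trial).
        for j, (i0, i1, _, phi_to) in enumerate(seg_bounds):
            if i1 < i0 + ns:
                continue  # stance truncated by trial end; no swing follows
            if j + 1 < len(seg_bounds):
                nxt_i0 = seg_bounds[j + 1][0]
                nxt_phi = seg_bounds[j + 1][2]
                nxt_h = events[j + 1]
            else:
                nxt_h = events[j] + period
                se = nxt_h + stance_len
                anchor = xf(nxt_h) + 0.5 * (xf(se) - xf(nxt_h))
                nxt_phi = float(_closure_phi(np.array([anchor - xf(nxt_h)]),
                                             np.array([k_hs]), lt, ls)[0])
                nxt_i0 = n
            gidx = np.arange(i1, min(nxt_i0, n))
            if len(gidx) == 0:
                continue
            swing_start = events[j] + stance_len
            u = (t[gidx] - swing_start) / (nxt_h - swing_start)
            u = np.clip(u, 0.0, 1.0)
            k[leg][gidx] = _swing_template(u, k_to, k_sw, k_hs)
            phi[leg][gidx] = _cos_interp(u, phi_to, nxt_phi)

        # Lead-in: blend from neutral standing into the first heel strike.
        i0_first, _, phi_first, _ = seg_bounds[0]
        pre = np.arange(0, i0_first)
        blend = _smoothstep((t[pre] - t_walk) / max(events[0] - t_walk, 1e-6))
        phi[leg][pre] = blend * phi_first
        k[leg][pre] = blend * k_hs

    sigma = {leg: phi[leg] - np.deg2rad(k[leg]) for leg in LEGS}
    knee_pos = {}
    ankle_pos = {}
    for leg in LEGS:
        knee_pos[leg] = hip + lt * np.column_stack(
            [np.sin(phi[leg]), -np.cos(phi[leg])]
        )
        ankle_pos[leg] = knee_pos[leg] + ls * np.column_stack(
            [np.sin(sigma[leg]), -np.cos(sigma[leg])]
        )

    return TrialKinematics(
        t=t,
        fs=cfg.fs,
        direction=direction,
        true_speed=float(v_cms),
        gait_period=period,
        thigh_len=lt,
        shank_len=ls,
        hip=hip,
        thigh_angle=phi,
        shank_angle=sigma,
        knee_pos=knee_pos,
        ankle_pos=ankle_pos,
        flexion_deg=k,
        hs_times={leg: np.asarray(hs[leg]) for leg in LEGS},
        stance_windows=stance_windows,
        template={"a1": a1, "a2": a2, "k_hs": k_hs, "k_to": k_to, "k_sw": k_sw},
        config=cfg,
    )
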