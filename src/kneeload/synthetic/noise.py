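"""Measurement-noise presets for the synthetic gait laboratory.

``none`` produces ideal streams (used for round-trip validation of the
estimators); ``realistic`` adds soft-tissue-like low-frequency orientation
noise to the IMUs, white accelerometer noise, pixel jitter and
direction-dependent occlusion to the keypoints, and a 10% trial-invalidity
rate, so that cohort-level estimator errors resemble real portable captures.
"""

from __future__ import annotations

from dataclasses import dataclass

from ..errors import InvalidArgumentError


@dataclass(frozen=True)
class NoiseProfile:
    name: str
    orientation_deg: float = 0.0  # SD of low-passed angular noise per axis
    accel_ms2: float = 0.0  # SD of white accelerometer noise per axis
    px_jitter: float = 0.0  # SD of keypoint pixel jitter
    occlusion: bool = False  # far-leg occlusion episodes in video
    occlusion_bias_px: float = 0.0  # keypoint bias toward the near leg
    p_invalid: float = 0.0  # Bernoulli trial-invalidity probability


NOISE_NONE = NoiseProfile(name="none")
NOISE_REALISTIC = NoiseProfile(
    name="realistic",
    orientation_deg=2.0,
    accel_ms2=0.6,
    px_jitter=1.5,
    occlusion=True,
    occlusion_bias_px=3.0,
    p_invalid=0.1,
)

_PRESETS = {p.name: p for p in (NOISE_NONE, NOISE_REALISTIC)}


def get_noise_profile(name: str) -> NoiseProfile:
    try:
        return _PRESETS[name]
    except KeyError:
        raise InvalidArgumentError(
            f"unknown noise profile {name!r}; available: {sorted(_PRESETS)}"
        ) from None
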