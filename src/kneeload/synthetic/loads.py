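"""Ground-truth surrogate for the musculoskeletal contact-force pipeline.

Real studies obtain knee joint contact force (KJCF) curves from
musculoskeletal simulation. The synthetic laboratory replaces that pipeline
with a generative linear model: each trial's loading-response (LR) and
terminal-extension (TE) summed-compartment peak heights are linear in
(mass, height, age, sex, walking speed, KFA predictor), split between the
medial and lateral compartments by a medial share, and rendered as two
raised-cosine bumps over the stance phase. The linear coefficients are what
the downstream regression models should recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import InvalidArgumentError
from ..gait_features import RESPONSE_VARIABLES
from ..timeseries import KjcfCurvePair
from .cohort import SubjectProfile

#: Predictor order used throughout the package.
PREDICTOR_ORDER = ("mass", "height", "age", "sex", "speed", "kfa")


@dataclass(frozen=True)
class GenerativeLoadModel:
    """Linear generative model for the nine loading peaks.

    ``lr_coef``/``te_coef`` are coefficients over
    (mass kg, height cm, age y, sex {0,1}, speed cm/s, KFA deg) for the
    summed-compartment LR and TE peak heights in newtons. ``medial_share``
    is the fraction of the summed load carried medially; ``peak_noise_sd``
    the SD of Gaussian noise added to the realized peak heights; the timing
    fractions locate the two bumps within stance.
    """

    lr_coef: tuple[float, ...] = (14.0, 4.0, 2.0, 120.0, 9.5, 18.0)
    lr_intercept: float = -900.0
    te_coef: tuple[float, ...] = (12.0, 3.5, 1.5, 100.0, 7.5, 12.0)
    te_intercept: float = -700.0
    medial_share: float = 0.62
    medial_share_jitter: float = 0.03
    peak_noise_sd: float = 150.0
    lr_timing: float = 0.25
    te_timing: float = 0.75
    bump_halfwidth: float = 0.22  # fraction of stance

    def __post_init__(self) -> None:
        if not 0.0 < self.medial_share < 1.0:
            raise InvalidArgumentError("medial_share must lie in (0,1)")
        if not self.lr_timing < 0.5 < self.te_timing:
            raise InvalidArgumentError("need lr_timing < 0.5 < te_timing")
        if self.peak_noise_sd < 0:
            raise InvalidArgumentError("peak_noise_sd must be >= 0")

    def linear_peaks(self, x: np.ndarray) -> tuple[float, float]:
        """Noiseless summed LR and TE peak heights for predictor vector
        ``x`` ordered as :data:`PREDICTOR_ORDER`."""
        x = np.asarray(x, dtype=float)
        lr = float(np.dot(self.lr_coef, x) + self.lr_intercept)
        te = float(np.dot(self.te_coef, x) + self.te_intercept)
        return lr, te


@dataclass
class SynthesizedLoad:
    """One trial's generated stance loading curves and peak targets."""

    curves: KjcfCurvePair
    peaks_noiseless: dict[str, float]  # linear-model targets per response
    peaks_realized: dict[str, float]  # heights actually rendered in curves
    degenerate: bool  # a pre-clip peak prediction was <= 0


def _bump(n: int, center_frac: float, halfwidth_frac: float,
          height: float) -> np.ndarray:
    """Raised-cosine bump on n samples; its center snaps to the grid so the
    sampled maximum equals ``height`` exactly."""
    c = round(center_frac * (n - 1))
    w = max(2, round(halfwidth_frac * (n - 1)))
    i = np.arange(n)
    out = np.zeros(n)
    inside = np.abs(i - c) <= w
    out[inside] = height * 0.5 * (1.0 + np.cos(np.pi * (i[inside] - c) / w))
    return out


def _nine(lr_sum: float, te_sum: float, share: float) -> dict[str, float]:
    vals = {
        "lr_summed": lr_sum,
        "te_summed": te_sum,
        "lr_medial": share * lr_sum,
        "te_medial": share * te_sum,
        "lr_lateral": (1.0 - share) * lr_sum,
        "te_lateral": (1.0 - share) * te_sum,
    }
    for comp in ("summed", "medial", "lateral"):
        vals[f"max_{comp}"] = max(vals[f"lr_{comp}"], vals[f"te_{comp}"])
    assert set(vals) == set(RESPONSE_VARIABLES)
    return vals


def synthesize_kjcf(
    profile: SubjectProfile,
    true_speed: float,
    kfa_predictor: float,
    model: GenerativeLoadModel,
    seed: int | np.random.SeedSequence,
    n_samples: int = 64,
) -> SynthesizedLoad:
    """Generate medial/lateral stance loading curves for one trial.

    Peak heights are the generative model's linear predictions plus Gaussian
    noise (clipped at zero; a non-positive pre-clip prediction flags the
    trial degenerate). The two bumps do not overlap, so extracting peaks
    from the rendered curves recovers the realized heights exactly.
    """
    rng = np.random.default_rng(seed)
    x = np.array([profile.mass, profile.height, profile.age, float(profile.sex),
                  true_speed, kfa_predictor])
    lr_clean, te_clean = model.linear_peaks(x)
    lr = lr_clean + rng.normal(0.0, model.peak_noise_sd) if model.peak_noise_sd else lr_clean
    te = te_clean + rng.normal(0.0, model.peak_noise_sd) if model.peak_noise_sd else te_clean
    degenerate = bool(lr <= 0 or te <= 0 or lr_clean <= 0 or te_clean <= 0)
    lr, te = max(lr, 0.0), max(te, 0.0)

    share = float(np.clip(
        model.medial_share
        + (rng.normal(0.0, model.medial_share_jitter)
           if model.medial_share_jitter else 0.0),
        0.05, 0.95,
    ))
    realized = _nine(lr, te, share)
    noiseless = _nine(max(lr_clean, 0.0), max(te_clean, 0.0), model.medial_share)

    medial = (
        _bump(n_samples, model.lr_timing, model.bump_halfwidth, realized["lr_medial"])
        + _bump(n_samples, model.te_timing, model.bump_halfwidth, realized["te_medial"])
    )
    lateral = (
        _bump(n_samples, model.lr_timing, model.bump_halfwidth, realized["lr_lateral"])
        + _bump(n_samples, model.te_timing, model.bump_halfwidth, realized["te_lateral"])
    )
    return SynthesizedLoad(
        curves=KjcfCurvePair(medial=medial, lateral=lateral),
        peaks_noiseless=noiseless,
        peaks_realized=realized,
        degenerate=degenerate,
    )
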