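"""Synthetic study cohorts: demographics and comfortable walking speeds.

The default distributions emulate a healthy adult gait-laboratory cohort:
ages 20-45 years (29 +/- 6), body mass index 18.8-40.4 kg/m^2 (25.1 +/- 4.2),
male fraction 29/46, and a comfortable walking speed centred at 133.56 cm/s.
Ages and BMIs are drawn from truncated normals with those moments; mass is
derived from BMI and height.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ..errors import InvalidArgumentError

#: Fraction of male participants in the emulated cohort.
MALE_FRACTION = 29.0 / 46.0

AGE_MEAN, AGE_SD, AGE_RANGE = 29.0, 6.0, (20.0, 45.0)
BMI_MEAN, BMI_SD, BMI_RANGE = 25.1, 4.2, (18.8, 40.4)
SPEED_MEAN, SPEED_SD, SPEED_RANGE = 133.56, 20.0, (80.0, 200.0)
# Height (cm) by sex: coarse adult anthropometry, truncated to plausible range.
HEIGHT_BY_SEX = {0: (165.0, 6.5), 1: (178.0, 7.0)}
HEIGHT_RANGE = (150.0, 200.0)


@dataclass(frozen=True)
class SubjectProfile:
    """Demographics and anthropometrics of one simulated participant.

    ``sex`` is coded 0 = female, 1 = male; ``comfortable_speed`` is the
    self-selected walking speed in cm/s.
    """

    subject_id: str
    mass: float  # kg
    height: float  # cm
    age: float  # years
    sex: int  # 0 female, 1 male
    comfortable_speed: float  # cm/s

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.height <= 0 or self.age < 0:
            raise InvalidArgumentError("mass/height must be > 0 and age >= 0")
        if not 0 < self.comfortable_speed < 400:
            raise InvalidArgumentError("comfortable_speed must be in (0, 400) cm/s")
        if self.sex not in (0, 1):
            raise InvalidArgumentError("sex must be coded 0 (female) or 1 (male)")

    @property
    def bmi(self) -> float:
        return self.mass / (self.height / 100.0) ** 2


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float, size: int) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def sample_koa_cohort(n: int, seed: int) -> list[SubjectProfile]:
    """Draw an osteoarthritis-patient-like cohort used for pre-training:
    older, heavier and slower than the healthy cohort."""
    if n < 1:
        raise InvalidArgumentError("cohort size must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x60A]))
    sexes = (rng.random(n) < 0.45).astype(int)
    ages = _truncnorm(rng, 62.0, 8.0, 45.0, 80.0, size=n)
    bmis = _truncnorm(rng, 29.5, 4.5, 21.0, 42.0, size=n)
    speeds = _truncnorm(rng, 110.0, 18.0, 60.0, 170.0, size=n)
    profiles = []
    for i in range(n):
        mu, sd = HEIGHT_BY_SEX[int(sexes[i])]
        height = float(_truncnorm(rng, mu, sd, *HEIGHT_RANGE, size=1)[0])
        profiles.append(
            SubjectProfile(
                subject_id=f"K{i:03d}",
                mass=float(bmis[i] * (height / 100.0) ** 2),
                height=height,
                age=float(ages[i]),
                sex=int(sexes[i]),
                comfortable_speed=float(speeds[i]),
            )
        )
    return profiles


def sample_cohort(n: int, seed: int) -> list[SubjectProfile]:
    """Draw ``n`` subject profiles; deterministic under a fixed ``seed``.

    Mass is derived as BMI * (height/100)^2 so that the cohort BMI range is
    controlled directly, mirroring how gait-study cohorts are reported.
    """
    if n < 1:
        raise InvalidArgumentError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)
    sexes = (rng.random(n) < MALE_FRACTION).astype(int)
    ages = _truncnorm(rng, AGE_MEAN, AGE_SD, *AGE_RANGE, size=n)
    bmis = _truncnorm(rng, BMI_MEAN, BMI_SD, *BMI_RANGE, size=n)
    speeds = _truncnorm(rng, SPEED_MEAN, SPEED_SD, *SPEED_RANGE, size=n)
    profiles = []
    for i in range(n):
        mu, sd = HEIGHT_BY_SEX[int(sexes[i])]
        height = float(_truncnorm(rng, mu, sd, *HEIGHT_RANGE, size=1)[0])
        mass = float(bmis[i] * (height / 100.0) ** 2)
        profiles.append(
            SubjectProfile(
                subject_id=f"S{i:03d}",
                mass=mass,
                height=height,
                age=float(ages[i]),
                sex=int(sexes[i]),
                comfortable_speed=float(speeds[i]),
            )
        )
    return profiles
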