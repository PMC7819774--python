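"""LMS growth-reference engine.

Pediatric body size is referenced against age- and sex-specific LMS tables:
at each age the reference distribution of BMI is described by a Box-Cox
power ``L``, a median ``M`` (kg/m²), and a coefficient of variation ``S``.
A child's BMI maps to a z-score ("BMIz") via the standard LMS transform

    z = ((x / M)**L - 1) / (L * S)        for |L| > eps
    z = ln(x / M) / S                     for L ≈ 0

and z-scores map to percentiles through the standard-normal CDF.  This
module provides the forward and inverse transforms, age-continuous lookup
by linear interpolation, and conventional weight-status classification at
the 5th/85th/95th percentile cutoffs.
"""

from __future__ import annotations

import datetime as dt
from bisect import bisect_left
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.stats import norm

__all__ = [
    "Sex",
    "WeightStatus",
    "LMSRecord",
    "GrowthReference",
    "Anthropometry",
    "ChildProfile",
    "bmi",
    "lms_zscore",
    "lms_inverse",
    "interpolate_lms",
    "percentile_from_z",
    "classify_weight_status",
    "bmiz",
    "age_in_months",
    "LB_TO_KG",
]

#: Exact international avoirdupois pound, kg per lb.
LB_TO_KG = 0.45359237

#: Days per mean Gregorian month, used to convert date spans to months.
DAYS_PER_MONTH = 30.4375

#: |L| below this uses the logarithmic branch of the LMS transform.
L_EPS = 1e-7


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"

    @classmethod
    def coerce(cls, value) -> "Sex":
        """Accept 'male'/'female' strings (any case), 1/2 integer codes, or Sex."""
        if isinstance(value, cls):
            return value
        if isinstance(value, (int, np.integer)):
            if value == 1:
                return cls.MALE
            if value == 2:
                return cls.FEMALE
            raise ValueError(f"unknown sex code {value!r} (expected 1 or 2)")
        s = str(value).strip().lower()
        if s in ("male", "m", "1"):
            return cls.MALE
        if s in ("female", "f", "2"):
            return cls.FEMALE
        raise ValueError(f"unknown sex {value!r}")


class WeightStatus(str, Enum):
    UNDERWEIGHT = "underweight"
    NORMAL = "normal"
    OVERWEIGHT = "overweight"
    OBESITY = "obesity"


@dataclass(frozen=True)
class LMSRecord:
    """One row of an LMS reference: parameters at a single age.

    Parameters
    ----------
    sex : Sex
    age_months : float
        Age in months, >= 0.
    L : float
        Box-Cox power.
    M : float
        Median of the measure (BMI in kg/m²), > 0.
    S : float
        Coefficient of variation, > 0.
    """

    sex: Sex
    age_months: float
    L: float
    M: float
    S: float

    def __post_init__(self):
        if self.age_months < 0:
            raise ValueError(f"age_months must be >= 0, got {self.age_months}")
        if self.M <= 0:
            raise ValueError(f"M must be > 0, got {self.M}")
        if self.S <= 0:
            raise ValueError(f"S must be > 0, got {self.S}")


@dataclass
class GrowthReference:
    """Sex- and age-indexed LMS table with age-continuous lookup.

    ``records`` maps each sex to a list of LMSRecord strictly increasing in
    age; lookups are valid only inside each sex's age support.
    """

    records: dict[Sex, list[LMSRecord]]

    def __post_init__(self):
        for sex, recs in self.records.items():
            if len(recs) < 2:
                raise ValueError(f"need at least 2 records for {sex.value}")
            ages = [r.age_months for r in recs]
            if any(b <= a for a, b in zip(ages, ages[1:])):
                raise ValueError(f"ages not strictly increasing for {sex.value}")

    def age_support(self, sex: Sex) -> tuple[float, float]:
        recs = self.records[Sex.coerce(sex)]
        return recs[0].age_months, recs[-1].age_months

    def lookup(self, sex, age_months: float) -> LMSRecord:
        return interpolate_lms(self, sex, age_months)


@dataclass(frozen=True)
class Anthropometry:
    """A dated height/weight measurement (cm, kg)."""

    date: dt.date
    height_cm: float
    weight_kg: float

    def __post_init__(self):
        if not (40.0 < self.height_cm < 250.0):
            raise ValueError(f"height_cm {self.height_cm} outside (40, 250)")
        if not (5.0 < self.weight_kg < 300.0):
            raise ValueError(f"weight_kg {self.weight_kg} outside (5, 300)")

    @property
    def bmi(self) -> float:
        return bmi(self.weight_kg, self.height_cm)


@dataclass(frozen=True)
class ChildProfile:
    """Identity and baseline measurement of an enrolled child.

    Eligibility band defaults to ages 5-14 years at baseline.
    """

    child_id: str
    sex: Sex
    birth_date: dt.date
    baseline: Anthropometry
    eligibility_years: tuple[float, float] = field(default=(5.0, 14.0))

    def __post_init__(self):
        object.__setattr__(self, "sex", Sex.coerce(self.sex))
        if self.baseline.date < self.birth_date:
            raise ValueError("baseline date precedes birth date")
        lo, hi = self.eligibility_years
        age_y = self.age_months(self.baseline.date) / 12.0
        # hi+1: "age 14" means before the 15th birthday; ~1 week of slack
        # absorbs day-resolution birth dates at the band edges
        if not (lo - 0.02 <= age_y <= hi + 1):
            raise ValueError(
                f"baseline age {age_y:.1f} y outside eligibility band [{lo}, {hi}]"
            )

    def age_months(self, on_date: dt.date) -> float:
        return age_in_months(self.birth_date, on_date)


def age_in_months(birth_date: dt.date, on_date: dt.date) -> float:
    """Age as (on_date - birth_date) in days / 30.4375."""
    return (on_date - birth_date).days / DAYS_PER_MONTH


def bmi(weight_kg: float, height_cm: float) -> float:
    """Body mass index, kg/m²."""
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    h_m = height_cm / 100.0
    return weight_kg / (h_m * h_m)


def lms_zscore(x: float, rec: LMSRecord) -> float:
    """Box-Cox LMS z-score of measurement ``x`` against ``rec``."""
    if x <= 0:
        raise ValueError("measurement must be positive")
    if abs(rec.L) > L_EPS:
        return ((x / rec.M) ** rec.L - 1.0) / (rec.L * rec.S)
    return np.log(x / rec.M) / rec.S


def lms_inverse(z: float, rec: LMSRecord) -> float:
    """Measurement at z-score ``z``: inverse of :func:`lms_zscore`."""
    if abs(rec.L) > L_EPS:
        base = 1.0 + rec.L * rec.S * z
        if base <= 0:
            raise ValueError(
                f"z={z} outside the support of the Box-Cox reference (1+LSz<=0)"
            )
        return rec.M * base ** (1.0 / rec.L)
    return rec.M * np.exp(rec.S * z)


def interpolate_lms(ref: GrowthReference, sex, age_months: float) -> LMSRecord:
    """LMS parameters at an arbitrary age, linear in age per parameter."""
    sex = Sex.coerce(sex)
    recs = ref.records[sex]
    lo, hi = recs[0].age_months, recs[-1].age_months
    if not (lo <= age_months <= hi):
        raise ValueError(
            f"age {age_months:.1f} mo outside reference support [{lo}, {hi}] for {sex.value}"
        )
    ages = [r.age_months for r in recs]
    i = bisect_left(ages, age_months)
    if i < len(ages) and ages[i] == age_months:
        return recs[i]
    a, b = recs[i - 1], recs[i]
    w = (age_months - a.age_months) / (b.age_months - a.age_months)
    return LMSRecord(
        sex=sex,
        age_months=age_months,
        L=a.L + w * (b.L - a.L),
        M=a.M + w * (b.M - a.M),
        S=a.S + w * (b.S - a.S),
    )


def percentile_from_z(z: float) -> float:
    """Percentile (0-100) of a standard-normal z-score."""
    return 100.0 * float(norm.cdf(z))


def z_from_percentile(percentile: float) -> float:
    """Standard-normal z at a percentile in (0, 100)."""
    if not (0.0 < percentile < 100.0):
        raise ValueError("percentile must be in (0, 100)")
    return float(norm.ppf(percentile / 100.0))


def classify_weight_status(percentile: float) -> WeightStatus:
    """Conventional pediatric weight status at 5/85/95 percentile cutoffs.

    <5 underweight; [5, 85) normal; [85, 95) overweight; >=95 obesity.
    """
    if not (0.0 <= percentile <= 100.0):
        raise ValueError(f"percentile {percentile} outside [0, 100]")
    if percentile < 5.0:
        return WeightStatus.UNDERWEIGHT
    if percentile < 85.0:
        return WeightStatus.NORMAL
    if percentile < 95.0:
        return WeightStatus.OVERWEIGHT
    return WeightStatus.OBESITY


def bmiz(profile: ChildProfile, anthro: Anthropometry, ref: GrowthReference) -> float:
    """BMI z-score of one measurement for one child against a reference."""
    rec = interpolate_lms(ref, profile.sex, profile.age_months(anthro.date))
    return lms_zscore(anthro.bmi, rec)
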