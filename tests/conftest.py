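import datetime as dt
import math

import pytest

from pedizone.growth import (
    Anthropometry,
    ChildProfile,
    GrowthReference,
    LMSRecord,
    Sex,
    lms_inverse,
)
from pedizone.synthetic import make_lms_fixture

BASE_DATE = dt.date(2024, 1, 8)


@pytest.fixture(scope="session")
def ref() -> GrowthReference:
    """Analytic LMS reference with affine-in-age median BMI."""
    return make_lms_fixture()


@pytest.fixture(scope="session")
def flat_ref() -> GrowthReference:
    """Reference whose L, M, S are age-constant (M = 17.4, L = -1.5, S = 0.12).

    With this reference a child's BMIz depends only on BMI, which makes
    expected values hand-computable for rate and safety tests.
    """
    records = {}
    for sex in (Sex.MALE, Sex.FEMALE):
        records[sex] = [
            LMSRecord(sex=sex, age_months=a, L=-1.5, M=17.4, S=0.12)
            for a in (48.0, 120.0, 216.0)
        ]
    return GrowthReference(records)


def child_at_z(
    reference: GrowthReference,
    z: float,
    weight_kg: float | None = None,
    age_months: float = 120.0,
    sex: Sex = Sex.MALE,
    date: dt.date = BASE_DATE,
) -> ChildProfile:
    """A child whose baseline BMIz is exactly ``z`` against ``reference``.

    When ``weight_kg`` is given, height is solved so BMI lands on the
    z-implied value; otherwise height is 140 cm and weight is derived.
    """
    birth_date = date - dt.timedelta(days=round(age_months * 30.4375))
    age_realized = (date - birth_date).days / 30.4375  # day-resolution age
    rec = reference.lookup(sex, age_realized)
    target_bmi = lms_inverse(z, rec)
    if weight_kg is None:
        height_cm = 140.0
        weight_kg = target_bmi * (height_cm / 100.0) ** 2
    else:
        height_cm = 100.0 * math.sqrt(weight_kg / target_bmi)
    baseline = Anthropometry(date=date, height_cm=height_cm, weight_kg=weight_kg)
    return ChildProfile(
        child_id=f"z{z:+.2f}", sex=sex, birth_date=birth_date, baseline=baseline
    )
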