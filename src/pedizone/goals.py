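"""Energy and activity prescriptions.

Total energy expenditure is estimated as Harris-Benedict basal metabolic
rate times a physical activity level (PAL, default 1.4); the daily intake
goal subtracts a fixed deficit (default 250 kcal/d) to promote modest
weight loss or gain attenuation.  Activity goals ramp daily steps linearly
from a personal baseline to baseline + 6,000 steps/day.  Foods are
categorised green/yellow/red by calories per serving (Traffic Light
scheme); the calorie cutoffs are a convention and must be configured.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .growth import Sex

__all__ = [
    "HB_REVISED",
    "HB_ORIGINAL",
    "EnergyPrescription",
    "StepGoal",
    "TrafficLightConfig",
    "TrafficLightColor",
    "harris_benedict_bmr",
    "energy_goal",
    "step_goal",
    "traffic_light",
]

# Harris-Benedict coefficient sets: intercept, weight (kg), height (cm), age (y).
# Revised (Roza & Shizgal 1984) is the default; the original 1919 set is selectable.
HB_REVISED = {
    Sex.MALE: (88.362, 13.397, 4.799, 5.677),
    Sex.FEMALE: (447.593, 9.247, 3.098, 4.330),
}
HB_ORIGINAL = {
    Sex.MALE: (66.4730, 13.7516, 5.0033, 6.7550),
    Sex.FEMALE: (655.0955, 9.5634, 1.8496, 4.6756),
}


@dataclass(frozen=True)
class EnergyPrescription:
    """Daily energy prescription: BMR × PAL − deficit."""

    bmr_kcal_d: float
    pal: float
    tee_kcal_d: float
    deficit_kcal_d: float
    intake_goal_kcal_d: float

    def __post_init__(self):
        if self.intake_goal_kcal_d <= 0:
            raise ValueError("intake goal must be positive")


@dataclass(frozen=True)
class StepGoal:
    """Weekly step targets ramping from a personal baseline."""

    baseline_steps: int
    increment: int
    ramp_weeks: int
    weekly_targets: tuple[int, ...]


@dataclass(frozen=True)
class TrafficLightConfig:
    green_max_kcal: float
    yellow_max_kcal: float

    def __post_init__(self):
        if not (0 < self.green_max_kcal < self.yellow_max_kcal):
            raise ValueError("need 0 < green_max < yellow_max")


class TrafficLightColor(str, Enum):
    GREEN = "green"
    YELLOW = "yellow"
    RED = "red"


def harris_benedict_bmr(
    sex,
    weight_kg: float,
    height_cm: float,
    age_years: float,
    coefficients: dict | None = None,
) -> float:
    """Harris-Benedict basal metabolic rate, kcal/day.

    Default coefficients are the revised (Roza-Shizgal) set; pass
    ``coefficients=HB_ORIGINAL`` for the original 1919 equation.
    """
    if weight_kg <= 0 or height_cm <= 0 or age_years <= 0:
        raise ValueError("weight, height, and age must be positive")
    sex = Sex.coerce(sex)
    c0, cw, ch, ca = (coefficients or HB_REVISED)[sex]
    return c0 + cw * weight_kg + ch * height_cm - ca * age_years


def energy_goal(
    bmr_kcal_d: float, pal: float = 1.4, deficit: float = 250.0
) -> EnergyPrescription:
    """Daily intake goal: TEE (BMR × PAL) minus a fixed deficit."""
    if bmr_kcal_d <= 0 or pal <= 0:
        raise ValueError("bmr and pal must be positive")
    tee = bmr_kcal_d * pal
    goal = tee - deficit
    if goal <= 0:
        raise ValueError(f"intake goal {goal:.0f} kcal/d is not positive")
    return EnergyPrescription(
        bmr_kcal_d=bmr_kcal_d,
        pal=pal,
        tee_kcal_d=tee,
        deficit_kcal_d=deficit,
        intake_goal_kcal_d=goal,
    )


def step_goal(
    baseline_steps: int, increment: int = 6000, ramp_weeks: int = 8
) -> StepGoal:
    """Linear weekly ramp to baseline + increment steps/day.

    Week-k target (1-based) is baseline + round(increment * k / ramp_weeks).
    """
    if baseline_steps < 0 or increment < 0:
        raise ValueError("baseline and increment must be non-negative")
    if ramp_weeks < 1:
        raise ValueError("ramp_weeks must be >= 1")
    targets = tuple(
        baseline_steps + round(increment * (k + 1) / ramp_weeks)
        for k in range(ramp_weeks)
    )
    return StepGoal(
        baseline_steps=baseline_steps,
        increment=increment,
        ramp_weeks=ramp_weeks,
        weekly_targets=targets,
    )


def traffic_light(kcal_per_serving: float, cfg: TrafficLightConfig) -> TrafficLightColor:
    """Categorise a food by calories per serving.

    green: kcal < green_max; yellow: [green_max, yellow_max); red otherwise.
    """
    if kcal_per_serving < 0:
        raise ValueError("kcal must be non-negative")
    if kcal_per_serving < cfg.green_max_kcal:
        return TrafficLightColor.GREEN
    if kcal_per_serving < cfg.yellow_max_kcal:
        return TrafficLightColor.YELLOW
    return TrafficLightColor.RED
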