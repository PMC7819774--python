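"""Synthetic growth reference and cohort simulator.

Everything in the package is testable offline: an analytic LMS reference
(closed forms below, so expected z-scores are hand-computable) and a
simulated cohort of children in a 13-week remote weight-management program.

The default cohort emulates the pilot conditions: 10 children aged 5-14,
a 4 obesity / 4 overweight / 2 normal-weight baseline composition (eight of
ten at or above the 75th BMI percentile), per-child true BMIz change drawn
from Normal(-0.14, 0.17), weekly weigh-ins with additive scale noise and
random missingness, and daily pedometer logs.

Analytic reference closed forms (age ``a`` in months):

* male:   L = -1.5, S = 0.12, M(a) = 13.2 + 0.035 a
* female: L = -1.8, S = 0.13, M(a) = 13.0 + 0.036 a

M is affine in age, so linear interpolation between knots is exact.
Baseline height is drawn around an affine growth curve,
height(a) = 80 + 0.5 a cm, with 0.5 cm of linear growth over the study
(height gain is second-order at a 13-week horizon).

The simulated BMIz trajectory is linear from baseline to baseline + Δ over
the study — an assumption, not an observed shape; weigh-in weights are the
LMS-inverted weights at the interpolated height plus Gaussian scale noise.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_io import StepSeries, WeighInSeries, write_steps, write_weighins
from .growth import (
    Anthropometry,
    ChildProfile,
    GrowthReference,
    LMSRecord,
    Sex,
    bmiz,
    interpolate_lms,
    lms_inverse,
)
from .survey_stats import paired_t_from_pairs

__all__ = [
    "SimConfig",
    "SimulatedChild",
    "make_lms_fixture",
    "simulate_child",
    "simulate_cohort",
    "simulate_likert",
    "analyze_cohort",
    "empirical_power",
    "write_cohort_csvs",
]

_FIXTURE_PARAMS = {
    Sex.MALE: {"L": -1.5, "S": 0.12, "m0": 13.2, "m1": 0.035},
    Sex.FEMALE: {"L": -1.8, "S": 0.13, "m0": 13.0, "m1": 0.036},
}

# default baseline BMIz draw per weight-status stratum (uniform bounds):
# obesity >= 95th pct (z >= 1.645), overweight 85th-95th (1.036-1.645),
# normal-weight strata below the 75th percentile (the pilot's two
# normal-weight children were the only ones under the 75th).
_STATUS_Z_BOUNDS = {
    "obesity": (1.70, 2.20),
    "overweight": (1.05, 1.60),
    "normal": (0.30, 0.65),
}


@dataclass(frozen=True)
class SimConfig:
    """Conditions of the simulated program.

    Defaults mirror the pilot: 10 children, ages 5-14 years, true BMIz
    change ~ Normal(-0.14, 0.17) over 13 weeks, weekly weigh-ins with
    0.2 kg scale noise and 15% missingness.
    """

    seed: int
    n_children: int = 10
    age_range_years: tuple[float, float] = (5.0, 14.0)
    effect_mean_bmiz: float = -0.14
    effect_sd_bmiz: float = 0.17
    weighin_noise_kg: float = 0.2
    missingness_prob: float = 0.15
    duration_weeks: int = 13
    baseline_steps_range: tuple[int, int] = (3000, 8000)
    height_growth_cm: float = 0.5
    start_date: dt.date = dt.date(2024, 1, 8)
    prob_female: float = 0.6

    def __post_init__(self):
        if self.n_children < 1 or self.duration_weeks < 1:
            raise ValueError("n_children and duration_weeks must be >= 1")
        if not (0.0 <= self.missingness_prob < 1.0):
            raise ValueError("missingness_prob must be in [0, 1)")
        if self.weighin_noise_kg < 0:
            raise ValueError("weighin_noise_kg must be non-negative")


@dataclass(frozen=True)
class SimulatedChild:
    profile: ChildProfile
    status: str
    true_delta_bmiz: float
    weigh_ins: WeighInSeries
    steps: StepSeries
    post_anthro: Anthropometry


def make_lms_fixture(
    age_min_mo: float = 48.0, age_max_mo: float = 216.0, step_mo: float = 12.0
) -> GrowthReference:
    """Analytic LMS reference on a regular age grid (closed forms above)."""
    if age_max_mo <= age_min_mo or step_mo <= 0:
        raise ValueError("need age_max > age_min and step > 0")
    ages = np.arange(age_min_mo, age_max_mo + step_mo / 2, step_mo)
    if len(ages) < 2:
        raise ValueError("grid must contain at least 2 knots")
    records = {}
    for sex, p in _FIXTURE_PARAMS.items():
        records[sex] = [
            LMSRecord(
                sex=sex,
                age_months=float(a),
                L=p["L"],
                M=p["m0"] + p["m1"] * float(a),
                S=p["S"],
            )
            for a in ages
        ]
    return GrowthReference(records)


def fixture_median_bmi(sex, age_months: float) -> float:
    """Closed-form median BMI of the analytic fixture (for hand checks)."""
    p = _FIXTURE_PARAMS[Sex.coerce(sex)]
    return p["m0"] + p["m1"] * age_months


def _status_for_index(index: int) -> str:
    # 4 obesity / 4 overweight / 2 normal per block of 10, matching the
    # pilot composition for the default cohort size.
    r = index % 10
    if r < 4:
        return "obesity"
    if r < 8:
        return "overweight"
    return "normal"


def _child_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, index)))


def simulate_child(
    cfg: SimConfig, ref: GrowthReference, index: int
) -> SimulatedChild:
    """Simulate one child's 13-week monitoring record (deterministic per seed)."""
    rng = _child_rng(cfg.seed, index)
    status = _status_for_index(index)
    sex = Sex.FEMALE if rng.random() < cfg.prob_female else Sex.MALE
    age_years = rng.uniform(*cfg.age_range_years)
    age_mo0 = age_years * 12.0
    birth_date = cfg.start_date - dt.timedelta(days=round(age_mo0 * 30.4375))
    duration_days = cfg.duration_weeks * 7
    end_date = cfg.start_date + dt.timedelta(days=duration_days)

    z_lo, z_hi = _STATUS_Z_BOUNDS[status]
    z0 = rng.uniform(z_lo, z_hi)
    true_delta = rng.normal(cfg.effect_mean_bmiz, cfg.effect_sd_bmiz)

    h0 = 80.0 + 0.5 * age_mo0 + rng.normal(0.0, 2.0)

    def height_at(day: int) -> float:
        return h0 + cfg.height_growth_cm * day / duration_days

    def true_weight(day: int) -> float:
        on_date = cfg.start_date + dt.timedelta(days=day)
        age_mo = (on_date - birth_date).days / 30.4375
        z = z0 + true_delta * day / duration_days
        target_bmi = lms_inverse(z, interpolate_lms(ref, sex, age_mo))
        return target_bmi * (height_at(day) / 100.0) ** 2

    baseline = Anthropometry(
        date=cfg.start_date, height_cm=h0, weight_kg=true_weight(0)
    )
    profile = ChildProfile(
        child_id=f"sim{index:03d}", sex=sex, birth_date=birth_date, baseline=baseline
    )
    post = Anthropometry(
        date=end_date, height_cm=height_at(duration_days),
        weight_kg=true_weight(duration_days),
    )

    weigh_records = []
    for week in range(cfg.duration_weeks + 1):
        day = 7 * week
        noise = rng.normal(0.0, cfg.weighin_noise_kg) if cfg.weighin_noise_kg else 0.0
        keep = rng.random() >= cfg.missingness_prob
        if keep:
            weigh_records.append(
                (cfg.start_date + dt.timedelta(days=day), true_weight(day) + noise)
            )
    weigh_ins = WeighInSeries(profile.child_id, tuple(weigh_records))

    base_steps = int(rng.integers(*cfg.baseline_steps_range))
    step_records = []
    for day in range(duration_days + 1):
        # partial adherence to a +6000 steps/day ramp, with daily noise
        target_gain = 6000.0 * min(1.0, day / (8 * 7.0))
        steps = base_steps + 0.5 * target_gain + rng.normal(0.0, 800.0)
        step_records.append(
            (cfg.start_date + dt.timedelta(days=day), max(0, int(steps)))
        )
    steps = StepSeries(profile.child_id, tuple(step_records))

    return SimulatedChild(
        profile=profile,
        status=status,
        true_delta_bmiz=true_delta,
        weigh_ins=weigh_ins,
        steps=steps,
        post_anthro=post,
    )


def simulate_cohort(
    cfg: SimConfig, ref: GrowthReference
) -> tuple[list[SimulatedChild], dict]:
    """Simulate a cohort; returns (children, truth record of per-child Δ)."""
    children = [simulate_child(cfg, ref, i) for i in range(cfg.n_children)]
    truth = {
        "seed": cfg.seed,
        "effect_mean_bmiz": cfg.effect_mean_bmiz,
        "effect_sd_bmiz": cfg.effect_sd_bmiz,
        "children": {
            c.profile.child_id: {
                "true_delta_bmiz": c.true_delta_bmiz,
                "status": c.status,
                "sex": c.profile.sex.value,
            }
            for c in children
        },
    }
    return children, truth


def simulate_likert(n: int, probs, seed: int) -> tuple[int, ...]:
    """Multinomial response counts over K Likert levels (deterministic)."""
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 1 or np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("probs must be a simplex vector")
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    return tuple(int(c) for c in rng.multinomial(n, probs))


def analyze_cohort(
    children: list[SimulatedChild], ref: GrowthReference
) -> dict:
    """Pre/post BMIz paired analysis of a simulated (or ingested) cohort.

    Computes each child's baseline and end-of-study BMIz from the
    anthropometry pairs and runs the paired t-test on the differences.
    """
    pre = [bmiz(c.profile, c.profile.baseline, ref) for c in children]
    post = [bmiz(c.profile, c.post_anthro, ref) for c in children]
    t, df, p, mean_d, sd_d = paired_t_from_pairs(pre, post)
    return {
        "n": len(children),
        "mean_delta_bmiz": mean_d,
        "sd_delta_bmiz": sd_d,
        "t": t,
        "df": df,
        "p_two_sided": p,
    }


def empirical_power(
    cfg: SimConfig,
    ref: GrowthReference,
    n_reps: int = 40,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Monte-Carlo rejection rate and mean recovered Δ over replicate cohorts.

    Each replicate re-simulates a cohort under ``cfg`` with a distinct
    sub-seed and tests H0: mean ΔBMIz = 0 with the paired t at level alpha.
    Returns (power, grand mean of the recovered mean ΔBMIz).
    """
    rejections = 0
    means = []
    for rep in range(n_reps):
        rep_cfg = SimConfig(
            **{**cfg.__dict__, "seed": (cfg.seed * 100003 + rep) % (2**31 - 1)}
        )
        children, _ = simulate_cohort(rep_cfg, ref)
        res = analyze_cohort(children, ref)
        rejections += res["p_two_sided"] < alpha
        means.append(res["mean_delta_bmiz"])
    return rejections / n_reps, float(np.mean(means))


def write_cohort_csvs(
    children: list[SimulatedChild], truth: dict, outdir
) -> dict[str, Path]:
    """Write the standard CSVs (children/weighins/steps) plus truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    import pandas as pd

    children_rows = [
        {
            "child_id": c.profile.child_id,
            "sex": c.profile.sex.value,
            "birth_date": c.profile.birth_date.isoformat(),
            "baseline_date": c.profile.baseline.date.isoformat(),
            "height_cm": repr(c.profile.baseline.height_cm),
            "weight_kg": repr(c.profile.baseline.weight_kg),
        }
        for c in children
    ]
    paths = {
        "children": outdir / "children.csv",
        "weighins": outdir / "weighins.csv",
        "steps": outdir / "steps.csv",
        "truth": outdir / "truth.json",
    }
    pd.DataFrame(children_rows).to_csv(paths["children"], index=False)
    write_weighins(paths["weighins"], {c.profile.child_id: c.weigh_ins for c in children})
    write_steps(paths["steps"], {c.profile.child_id: c.steps for c in children})
    paths["truth"].write_text(json.dumps(truth, indent=2))
    return paths
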