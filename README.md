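# pedizone

A toolkit for family-based pediatric weight-management programs delivered
remotely: growth-reference z-scores, a child-tailored "adherence zone"
weight graph with objective safety triggers and energy-titration rules,
energy and step-goal prescriptions, wireless-scale/pedometer data
ingestion, Likert survey summaries, and a synthetic cohort simulator so
every component is testable without patient data.

## Who this is for

Researchers and clinical teams running (or simulating) behavioral weight
management in children aged roughly 5–14, where the clinical signal is the
BMI z-score (BMIz) rather than raw weight: children grow, so healthy
"weight maintenance" usually means a falling BMIz.

## The core model

**LMS z-scores.** Against an age- and sex-specific reference described by a
Box-Cox power `L`, median `M`, and coefficient of variation `S`, a BMI `x`
maps to

```
z = ((x/M)^L − 1) / (L·S)      (|L| > 1e−7)
z = ln(x/M) / S                (L ≈ 0)
```

with percentile `100·Φ(z)` and weight status classified at the conventional
5th/85th/95th percentile cutoffs.

**Adherence zone.** Each child gets a 6-pound band of acceptable weights.
At or above the 85th BMI percentile the baseline weight sits mid-band
(up to 3 lb of loss tolerated); below it, on the lower bound (maintenance
only). In long-term use the band is re-anchored every 6 months to the
weight preserving the zone's target BMIz at the child's new height.

**Safety and titration.** Losing more than 0.2 BMIz per 30 days, or more
than 2 lb within any 7-day span, raises a safety alert and forces an
*increase* in the energy prescription. Otherwise: *maintain* when BMIz is
at or below 0.25 (≈60th percentile), *reduce* when gaining above it.

**Goals.** Energy: Harris-Benedict BMR × physical activity level 1.4,
minus a 250 kcal/d deficit. Activity: ramp to baseline + 6,000 steps/day.
Foods categorise green/yellow/red by calories per serving (cutoffs are
configuration, not science).

**Surveys.** Likert items summarise as mean and *population* SD
(denominator n, the convention the bundled published tables follow), with
top-2-box endorsement on 4-point scales; the pre/post BMIz change uses a
paired t-test (sample SD).

## Worked example

```python
import datetime as dt
from pedizone import (Anthropometry, ChildProfile, build_zone,
                      energy_goal, harris_benedict_bmr, step_goal)
from pedizone.synthetic import make_lms_fixture

ref = make_lms_fixture()           # analytic LMS reference, no download
child = ChildProfile(
    child_id="c01", sex="male", birth_date=dt.date(2014, 1, 10),
    baseline=Anthropometry(dt.date(2024, 1, 8), height_cm=137.7, weight_kg=40.0),
)
zone = build_zone(child, ref)
print(f"zone: [{zone.lower_kg:.3f}, {zone.upper_kg:.3f}] kg, "
      f"allowance {zone.loss_allowance_lb:.0f} lb")

bmr = harris_benedict_bmr("male", 40.0, 140.0, 10.0)
rx = energy_goal(bmr, pal=1.4, deficit=250.0)
print(f"BMR {bmr:.1f} kcal/d -> intake goal {rx.intake_goal_kcal_d:.1f} kcal/d")
print("final step target:", step_goal(5000).weekly_targets[-1])
```

prints

```
zone: [38.639, 41.361] kg, allowance 3 lb
BMR 1239.3 kcal/d -> intake goal 1485.1 kcal/d
final step target: 11000
```

The zone is the baseline 40 kg ± 3 lb (this child's BMI is above the 85th
percentile, so a small loss is tolerated); the intake goal is
1239.3 × 1.4 − 250 kcal/d; the step goal is the 5,000-step baseline plus
6,000.

## Command line

```bash
pedizone simulate --seed 1 --out cohort/          # synthetic cohort CSVs
pedizone zone --children cohort/children.csv --lms cohort/lms_reference.csv \
              --weighins cohort/weighins.csv --out zones/
pedizone monitor --children cohort/children.csv --lms cohort/lms_reference.csv \
                 --weighins cohort/weighins.csv --out report.json
pedizone goals --children cohort/children.csv --lms cohort/lms_reference.csv \
               --out goals.json
pedizone survey --counts counts.csv --out summary.csv
```

Exit codes: 0 success, 2 input validation failure, 3 configuration error.

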