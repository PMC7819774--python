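# Methods

## Growth reference and BMIz

The package uses the standard three-parameter LMS description of a skewed
growth reference: at each age and sex, BMI is modelled so that
`z = ((x/M)^L − 1)/(L·S)` is standard normal, with the logarithmic limit
`z = ln(x/M)/S` taken when `|L| < 1e−7`. The inverse transform
`x = M·(1 + L·S·z)^{1/L}` is defined only while `1 + L·S·z > 0`; z-scores
outside that support raise a domain error rather than returning an
extrapolated value.

L, M and S are interpolated **linearly in age (months), per parameter**,
between table knots. Linear interpolation is monotone-preserving and exact
on the affine-in-age synthetic reference used in tests; for real
references on a fine (monthly) grid the interpolation error is far below
measurement noise. Age is computed as calendar days divided by 30.4375
(the mean Gregorian month), which makes every z-score reproducible from
dates alone.

Weight status uses the conventional pediatric percentile cutoffs — under 5
underweight, 5–85 normal, 85–95 overweight, 95+ obesity — with half-open
intervals (85.0 is overweight, 95.0 is obesity).

Units are kg and cm everywhere inside the library. Pounds appear only at
the zone interface, converted with the exact international pound,
1 lb = 0.45359237 kg.

## The adherence zone

Each child's acceptable weights form a band exactly 6 lb wide:

* baseline BMI percentile ≥ 85: band = baseline weight ± 3 lb. A small
  loss is tolerated for children who are overweight or have obesity.
* baseline BMI percentile < 85: band = [baseline, baseline + 6 lb]. The
  anchoring here is a design choice: the program promotes weight
  maintenance, so a child without the loss allowance sits on the lower
  bound, leaving the whole band for growth-related gain.

Zone bounds are closed on both sides: a weigh-in exactly on a bound counts
as adherent.

The zone's **target BMIz** is `max(baseline BMIz, 0.25)`. For children
above 0.25 this preserves their current status when the band is re-anchored
for height growth (the long-term trajectory toward 0.25 is driven by the
titration rules, not by zone revisions); for children at or below 0.25 the
target is 0.25 itself, consistent with the maintenance rule under which
such children grow into their weight. Re-anchoring solves for the weight
whose BMIz equals the target at the new height and age (LMS inversion, then
`weight = BMI·(height/100)²`), so the adjustment is idempotent at fixed
height, age and target. Two operating modes exist: `pilot_13wk` (default)
never revises the zone — a 13-week program ends before the 6-month revision
interval — and `long_term` revises once at least 183 days have elapsed,
or earlier when forced.

## Safety criteria and titration

Two objective safety triggers, both configurable with these defaults:

* **Excessive BMIz loss**: trailing-window BMIz rate below −0.2 per
  30 days. The default rate estimator is the endpoint difference between
  the earliest and latest weigh-in inside the trailing 30-day window,
  linearly rescaled to exactly 30 days; an OLS-slope estimator is
  selectable where series are noisy. Fewer than two in-window weigh-ins,
  or a span under 7 days, yields an *undefined* rate — reported as
  insufficient data, never as an alert.
* **Excessive weekly loss**: more than 2 lb lost between any two weigh-ins
  at most 7 days apart.

Both comparisons carry a 1e−9 guard so a series sitting exactly on a
threshold cannot trip it through floating-point noise in the LMS round
trip: a child losing exactly 2 lb/week never alerts, 2.01 lb/week always
does.

Heights between stadiometer measurements are interpolated linearly in time
for scale-only weigh-ins (constant outside the measured span).

The titration decision is a total function of (BMIz level, 30-day rate),
evaluated in precedence order: rate < −0.2 → **increase**; BMIz ≤ 0.25 →
**maintain**; rate > 0 above the threshold → **reduce**; otherwise
**maintain**. Any active safety alert overrides the table and forces an
increase. Exactly one rule fires per evaluation, verified against a
brute-force case analysis on a 10⁴-point grid.

## Goals

Basal metabolic rate uses the Harris-Benedict equation; the coefficient
set is configurable, with the revised (Roza–Shizgal) coefficients as the
default and the original 1919 set selectable — suitable references name the
equation without fixing the variant, and the revised set is the common
modern choice. Total energy expenditure is BMR × PAL (default 1.4,
reflecting low baseline activity), and the intake goal subtracts a fixed
deficit (default 250 kcal/d).

Step goals ramp linearly from a personal baseline to baseline + 6,000
steps/day over a configurable number of weeks (default 8, one step per
counseling session); week-k's target is `baseline + round(6000·k/ramp)`,
so targets are non-decreasing and end exactly at baseline + 6,000.

Traffic-light calorie cutoffs per serving vary by source and are therefore
configuration with no scientific default; the CLI convention is 20/50 kcal.
Categories are half-open: a food at a cutoff takes the higher category.

## Data ingestion

Duplicate anthropometric measures follow the two-then-three protocol: two
measures agreeing within 0.5 units are averaged; otherwise a third is
required and the closest two of the three are averaged. When the third
measure is equidistant from both, it is averaged with the *second*
measurement (later measurements presumed more careful) — a deterministic
tie-break the protocol itself leaves open. Supplying a third measure when
none is required, or omitting one when required, is a protocol error.

Same-day multiple scale transmissions collapse to the earliest (the
morning, post-void weighing convention), configurable to the mean; a
warning is always emitted. Step-log gaps stay missing — never imputed as
zero. Weekly weigh-in adherence counts half-open 7-day bins
`[start+7k, start+7(k+1))` containing at least one weigh-in.

Malformed CSV rows are collected and reported together with 1-based line
numbers (header = line 1).

## Survey statistics

Likert items summarise with the **population** SD (denominator n): the
bundled published tables only reproduce under that convention (e.g. counts
4,0,0,0,0,6 → SD √6 ≈ 2.449 → printed 2.4, where the sample SD would give
2.6). The paired t-test, by contrast, uses the sample SD of the
differences; both conventions deliberately coexist. Items with missing
responses use their own response total as n for mean/SD but the stated
respondent N as the endorsement denominator. Percentages round half-up.

The bundled child-item rows are internally inconsistent as published
(counts summing past the respondent total; dispersions matching neither SD
convention — plausibly standard errors). They load with a validation
warning and are excluded from reproduction checks.

The paired t recomputed from the published pilot summary (mean −0.14,
SD 0.17, n 10) gives t ≈ −2.604, p ≈ .029; the originally printed p of
.025 presumably came from unrounded data and is not reproducible from the
rounded summary, so no check asserts it.

## Synthetic cohort

The simulator emulates the pilot's conditions: 10 children aged 5–14,
composition 4 obesity / 4 overweight / 2 normal weight (strata drawn
uniformly in BMIz within 1.70–2.20, 1.05–1.60 and 0.30–0.65 respectively,
so eight of ten sit at or above the 75th percentile), true per-child BMIz
change drawn from Normal(−0.14, 0.17) over 13 weeks, weekly weigh-ins with
additive Gaussian scale noise (0.2 kg) and 15% missingness, and daily step
logs from a Uniform(3000, 8000) baseline. The BMIz trajectory is linear in
time and height grows 0.5 cm linearly over the study — both assumptions,
not observed shapes; they are config-exposed. Pre/post anthropometry pairs
are noise-free (the duplicate-measurement protocol suppresses measurement
error), so endpoint BMIz change equals the true draw by construction.

Seeding: a single master seed; each child uses an independent substream
via `SeedSequence((seed, index))`, so cohorts are reproducible
element-wise and extending n does not reshuffle existing children.

What passing tests show — and don't: the simulator validates the pipeline
arithmetic (ingestion → BMIz → paired t recovers the generating effect;
power ≈ 1 at n = 200 over 20 replicates, and well below 1 at the pilot's
n = 10) but says nothing about behavioural realism: no adherence decay,
weekend effects, or diet dynamics are modelled.

Problem sizes in the acceptance script (cohorts of 200 × 20 replicates for
recovery/power; 10 × 40 replicates for pilot-scale power) were chosen so
Monte-Carlo error is small relative to the quantities reported
(SE of the grand mean ≈ 0.003 BMIz) while the whole run stays in seconds.

## Known limitations

* No WHO reference support and no extended BMIz above the 97th percentile,
  where z-scores are known to compress.
* The zone-anchoring rule below the 85th percentile and the equidistant
  tie-break in reconciliation are documented conventions, not published
  prescriptions.
* The rate estimator sees only scale weigh-ins; a child gaining height
  rapidly between stadiometer visits will have slightly stale interpolated
  heights.
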