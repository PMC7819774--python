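"""Adherence-zone weight-graph engine.

A child's acceptable weights are a fixed 6-pound band plotted over time.
The band is anchored at the baseline weight: children at or above the 85th
BMI percentile get a ±3 lb band (a small loss allowance), children below it
a [0, +6] lb band (weight maintenance; growth-related gain allowed).  In
long-term use the band is re-anchored every 6 months to the weight that
preserves the zone's target BMIz at the child's new height and age.

Safety criteria watch for rapid or excessive loss: more than 0.2 BMIz lost
per 30 days, or more than 2 lb lost within any trailing 7-day span.  A
rule-based titration turns the current BMIz level and its 30-day rate into
an energy-intake action (increase / maintain / reduce); any active safety
alert overrides the rules and forces an increase.
"""

from __future__ import annotations

import datetime as dt
import json
import warnings
from dataclasses import dataclass, field, replace

from .data_io import WeighInSeries, weekly_adherence
from .growth import (
    LB_TO_KG,
    Anthropometry,
    ChildProfile,
    GrowthReference,
    bmi,
    bmiz,
    interpolate_lms,
    lms_inverse,
    lms_zscore,
    percentile_from_z,
)

__all__ = [
    "ZoneSpec",
    "SafetyAlert",
    "TitrationDecision",
    "GraphSeries",
    "MonitorConfig",
    "build_zone",
    "adjust_zone_for_height",
    "classify_weighin",
    "interpolate_height",
    "bmiz_rate",
    "safety_check",
    "titrate",
    "evaluate_titration",
    "weekly_adherence_report",
    "graph_series",
    "plot_weight_graph",
]

ZONE_WIDTH_LB = 6.0
LOSS_ALLOWANCE_LB = 3.0
MAINTENANCE_BMIZ = 0.25
EXCESSIVE_LOSS_BMIZ_PER_30D = 0.2
MAX_WEEKLY_LOSS_LB = 2.0


@dataclass(frozen=True)
class MonitorConfig:
    """Tunable thresholds of the zone/safety/titration rules.

    Defaults are the program's stated values; ``mode='pilot_13wk'``
    disables 6-month zone revision (a 13-week program never reaches one),
    ``mode='long_term'`` enables it.
    """

    width_lb: float = ZONE_WIDTH_LB
    loss_allowance_lb: float = LOSS_ALLOWANCE_LB
    loss_allowance_pctile: float = 85.0
    maintenance_bmiz: float = MAINTENANCE_BMIZ
    excessive_loss_z: float = EXCESSIVE_LOSS_BMIZ_PER_30D
    max_weekly_loss_lb: float = MAX_WEEKLY_LOSS_LB
    rate_window_days: int = 30
    rate_estimator: str = "endpoint"  # or "regression"
    mode: str = "pilot_13wk"  # or "long_term"
    revision_interval_days: int = 183  # ~6 months


@dataclass(frozen=True)
class ZoneSpec:
    """A dated acceptable-weight band for one child."""

    child_id: str
    effective_date: dt.date
    anchor_weight_kg: float
    lower_kg: float
    upper_kg: float
    width_lb: float
    loss_allowance_lb: float
    target_bmiz: float
    revision_index: int = 0

    def __post_init__(self):
        width_kg = self.width_lb * LB_TO_KG
        if abs((self.upper_kg - self.lower_kg) - width_kg) > 1e-9:
            raise ValueError("zone width does not equal width_lb in kg")
        if not (self.lower_kg <= self.anchor_weight_kg <= self.upper_kg):
            raise ValueError("anchor weight outside zone")

    @property
    def lower_lb(self) -> float:
        return self.lower_kg / LB_TO_KG

    @property
    def upper_lb(self) -> float:
        return self.upper_kg / LB_TO_KG


@dataclass(frozen=True)
class SafetyAlert:
    """A triggered safety criterion over a dated window.

    ``magnitude`` is ΔBMIz per 30 d (negative) for ``excessive_bmiz_loss``
    or pounds lost per trailing 7-day span for ``excessive_weekly_loss``.
    """

    kind: str  # "excessive_bmiz_loss" | "excessive_weekly_loss"
    window_start: dt.date
    window_end: dt.date
    magnitude: float

    def __post_init__(self):
        if self.window_end <= self.window_start:
            raise ValueError("alert window must have positive length")


@dataclass(frozen=True)
class TitrationDecision:
    """Energy-intake action with the single rule that fired."""

    action: str  # "increase" | "maintain" | "reduce"
    rule_fired: str
    bmiz_now: float
    bmiz_rate_per_30d: float | None


@dataclass(frozen=True)
class GraphSeries:
    """Plottable weight-graph series (pounds) with step-constant zone bounds."""

    child_id: str
    dates: tuple[dt.date, ...]
    observed_weights_lb: tuple[float, ...]
    zone_lower_lb: tuple[float, ...]
    zone_upper_lb: tuple[float, ...]

    def to_json(self, alerts: list[SafetyAlert] | None = None) -> str:
        payload = {
            "child_id": self.child_id,
            "dates": [d.isoformat() for d in self.dates],
            "weights_lb": list(self.observed_weights_lb),
            "zone_lower_lb": list(self.zone_lower_lb),
            "zone_upper_lb": list(self.zone_upper_lb),
            "alerts": [
                {
                    "kind": a.kind,
                    "window_start": a.window_start.isoformat(),
                    "window_end": a.window_end.isoformat(),
                    "magnitude": a.magnitude,
                }
                for a in (alerts or [])
            ],
        }
        return json.dumps(payload, indent=2)


def _anchor_to_bounds(
    anchor_kg: float, allow_loss: bool, cfg: MonitorConfig
) -> tuple[float, float]:
    width_kg = cfg.width_lb * LB_TO_KG
    if allow_loss:
        half = cfg.loss_allowance_lb * LB_TO_KG
        return anchor_kg - half, anchor_kg - half + width_kg
    return anchor_kg, anchor_kg + width_kg


def build_zone(
    profile: ChildProfile,
    ref: GrowthReference,
    cfg: MonitorConfig = MonitorConfig(),
) -> ZoneSpec:
    """Construct the baseline adherence zone for a child.

    The band is 6 lb wide.  At or above the 85th BMI percentile the baseline
    weight sits mid-band (loss of up to 3 lb tolerated); below it the
    baseline weight sits on the lower bound (no loss, growth-related gain
    within the band).  The zone's target BMIz is the larger of the baseline
    BMIz and the 0.25 maintenance threshold.
    """
    rec = interpolate_lms(ref, profile.sex, profile.age_months(profile.baseline.date))
    z0 = lms_zscore(profile.baseline.bmi, rec)
    pct = percentile_from_z(z0)
    allow_loss = pct >= cfg.loss_allowance_pctile
    anchor = profile.baseline.weight_kg
    lower, upper = _anchor_to_bounds(anchor, allow_loss, cfg)
    return ZoneSpec(
        child_id=profile.child_id,
        effective_date=profile.baseline.date,
        anchor_weight_kg=anchor,
        lower_kg=lower,
        upper_kg=upper,
        width_lb=cfg.width_lb,
        loss_allowance_lb=cfg.loss_allowance_lb if allow_loss else 0.0,
        target_bmiz=max(z0, cfg.maintenance_bmiz),
        revision_index=0,
    )


def adjust_zone_for_height(
    zone: ZoneSpec,
    new_anthro: Anthropometry,
    profile: ChildProfile,
    ref: GrowthReference,
    cfg: MonitorConfig = MonitorConfig(),
    force: bool = False,
) -> ZoneSpec:
    """Re-anchor the zone after height growth (6-month revision).

    The new anchor is the weight at which the child's BMIz equals the zone's
    target BMIz given the new height and age; band placement and width are
    unchanged in form.  In pilot mode (or before the revision interval has
    elapsed) the call must be forced.
    """
    due = (new_anthro.date - zone.effective_date).days >= cfg.revision_interval_days
    if not force:
        if cfg.mode == "pilot_13wk":
            raise ValueError("zone revision disabled in pilot_13wk mode (use force)")
        if not due:
            raise ValueError(
                "zone revision not yet due "
                f"(interval {cfg.revision_interval_days} d); use force to override"
            )
    if new_anthro.height_cm < profile.baseline.height_cm - 0.5:
        warnings.warn(
            f"{zone.child_id}: height decreased beyond measurement tolerance "
            f"({profile.baseline.height_cm} -> {new_anthro.height_cm} cm); "
            "anchor recomputed anyway",
            stacklevel=2,
        )
    rec = interpolate_lms(ref, profile.sex, profile.age_months(new_anthro.date))
    target_bmi = lms_inverse(zone.target_bmiz, rec)
    anchor = target_bmi * (new_anthro.height_cm / 100.0) ** 2
    lower, upper = _anchor_to_bounds(anchor, zone.loss_allowance_lb > 0, cfg)
    return replace(
        zone,
        effective_date=new_anthro.date,
        anchor_weight_kg=anchor,
        lower_kg=lower,
        upper_kg=upper,
        revision_index=zone.revision_index + 1,
    )


def classify_weighin(zone: ZoneSpec, weight_kg: float) -> str:
    """'below', 'in_zone' (bounds inclusive), or 'above'."""
    if weight_kg < zone.lower_kg:
        return "below"
    if weight_kg > zone.upper_kg:
        return "above"
    return "in_zone"


def interpolate_height(
    profile: ChildProfile,
    on_date: dt.date,
    later: Anthropometry | None = None,
) -> float:
    """Height (cm) at a date, linear between baseline and a later stadiometer
    measurement; constant outside the measured span."""
    h0, d0 = profile.baseline.height_cm, profile.baseline.date
    if later is None or later.date == d0:
        return h0
    h1, d1 = later.height_cm, later.date
    if on_date <= d0:
        return h0
    if on_date >= d1:
        return h1
    frac = (on_date - d0).days / (d1 - d0).days
    return h0 + frac * (h1 - h0)


def _series_bmiz(
    profile: ChildProfile,
    weigh_ins: WeighInSeries,
    ref: GrowthReference,
    later_anthro: Anthropometry | None = None,
) -> list[tuple[dt.date, float]]:
    out = []
    for date, w in weigh_ins.records:
        h = interpolate_height(profile, date, later_anthro)
        rec = interpolate_lms(ref, profile.sex, profile.age_months(date))
        out.append((date, lms_zscore(bmi(w, h), rec)))
    return out


def bmiz_rate(
    profile: ChildProfile,
    weigh_ins: WeighInSeries,
    ref: GrowthReference,
    later_anthro: Anthropometry | None = None,
    window_days: int = 30,
    estimator: str = "endpoint",
    as_of: dt.date | None = None,
) -> float | None:
    """ΔBMIz per ``window_days`` over the trailing window, or None.

    ``endpoint`` (default): the BMIz difference between the earliest and
    latest observation inside the trailing window, linearly rescaled to
    exactly ``window_days``.  ``regression``: OLS slope of BMIz on time,
    scaled to the window.  Returns None (undefined, not an alert) with
    fewer than 2 in-window weigh-ins or a span under 7 days.
    """
    if not weigh_ins.records:
        return None
    end = as_of or weigh_ins.records[-1][0]
    start = end - dt.timedelta(days=window_days)
    zs = [
        (d, z)
        for d, z in _series_bmiz(profile, weigh_ins, ref, later_anthro)
        if start <= d <= end
    ]
    if len(zs) < 2:
        return None
    span = (zs[-1][0] - zs[0][0]).days
    if span < 7:
        return None
    if estimator == "endpoint":
        return (zs[-1][1] - zs[0][1]) * window_days / span
    if estimator == "regression":
        import numpy as np

        t = np.array([(d - zs[0][0]).days for d, _ in zs], dtype=float)
        z = np.array([v for _, v in zs])
        slope = np.polyfit(t, z, 1)[0]
        return float(slope * window_days)
    raise ValueError(f"unknown estimator {estimator!r}")


def safety_check(
    profile: ChildProfile,
    weigh_ins: WeighInSeries,
    ref: GrowthReference,
    later_anthro: Anthropometry | None = None,
    cfg: MonitorConfig = MonitorConfig(),
) -> list[SafetyAlert]:
    """Evaluate the objective safety criteria on a weigh-in series.

    * ``excessive_bmiz_loss``: trailing-window BMIz rate below
      −``cfg.excessive_loss_z`` per 30 days.
    * ``excessive_weekly_loss``: any weight drop above
      ``cfg.max_weekly_loss_lb`` between two weigh-ins at most 7 days apart.
    """
    alerts: list[SafetyAlert] = []
    if not weigh_ins.records:
        return alerts

    rate = bmiz_rate(
        profile,
        weigh_ins,
        ref,
        later_anthro,
        window_days=cfg.rate_window_days,
        estimator=cfg.rate_estimator,
    )
    # 1e-9 guard: a rate sitting exactly on the threshold must not trip it
    # through floating-point noise in the LMS round trip
    if rate is not None and rate < -(cfg.excessive_loss_z + 1e-9):
        end = weigh_ins.records[-1][0]
        alerts.append(
            SafetyAlert(
                kind="excessive_bmiz_loss",
                window_start=end - dt.timedelta(days=cfg.rate_window_days),
                window_end=end,
                magnitude=rate,
            )
        )

    recs = weigh_ins.records
    max_loss_kg = cfg.max_weekly_loss_lb * LB_TO_KG
    for j in range(1, len(recs)):
        dj, wj = recs[j]
        for i in range(j - 1, -1, -1):
            di, wi = recs[i]
            if (dj - di).days > 7:
                break
            loss_kg = wi - wj
            if loss_kg > max_loss_kg + 1e-9:
                alerts.append(
                    SafetyAlert(
                        kind="excessive_weekly_loss",
                        window_start=di,
                        window_end=dj,
                        magnitude=loss_kg / LB_TO_KG,
                    )
                )
    return alerts


def titrate(
    bmiz_now: float,
    bmiz_rate_per_30d: float,
    threshold_z: float = MAINTENANCE_BMIZ,
    excessive_loss_z: float = EXCESSIVE_LOSS_BMIZ_PER_30D,
    gain_eps: float = 1e-9,
) -> TitrationDecision:
    """Energy-intake titration from BMIz level and 30-day rate.

    Rules, in precedence order: (1) rate below −excessive_loss_z →
    increase; (2) BMIz at or below the maintenance threshold → maintain
    (the child should grow into the weight, not restrict); (3) gaining
    (rate > 0) above the threshold → reduce; (4) otherwise maintain.
    """
    import math

    if not (math.isfinite(bmiz_now) and math.isfinite(bmiz_rate_per_30d)):
        raise ValueError("bmiz_now and bmiz_rate_per_30d must be finite")
    if bmiz_rate_per_30d < -excessive_loss_z:
        action, rule = "increase", "excessive_loss"
    elif bmiz_now <= threshold_z:
        action, rule = "maintain", "at_or_below_threshold"
    elif bmiz_rate_per_30d > gain_eps:
        action, rule = "reduce", "gaining_above_threshold"
    else:
        action, rule = "maintain", "maintenance_above_threshold"
    return TitrationDecision(
        action=action,
        rule_fired=rule,
        bmiz_now=bmiz_now,
        bmiz_rate_per_30d=bmiz_rate_per_30d,
    )


def evaluate_titration(
    profile: ChildProfile,
    weigh_ins: WeighInSeries,
    ref: GrowthReference,
    later_anthro: Anthropometry | None = None,
    cfg: MonitorConfig = MonitorConfig(),
) -> tuple[TitrationDecision | None, list[SafetyAlert]]:
    """Full monitoring evaluation: safety alerts + titration decision.

    Any active safety alert forces an increase (safety overrides the rate
    rules).  Returns (None, alerts) when BMIz cannot be evaluated.
    """
    alerts = safety_check(profile, weigh_ins, ref, later_anthro, cfg)
    if not weigh_ins.records:
        return None, alerts
    last_date, last_w = weigh_ins.records[-1]
    h = interpolate_height(profile, last_date, later_anthro)
    rec = interpolate_lms(ref, profile.sex, profile.age_months(last_date))
    z_now = lms_zscore(bmi(last_w, h), rec)
    rate = bmiz_rate(
        profile,
        weigh_ins,
        ref,
        later_anthro,
        window_days=cfg.rate_window_days,
        estimator=cfg.rate_estimator,
    )
    if alerts:
        decision = TitrationDecision(
            action="increase",
            rule_fired="excessive_loss",
            bmiz_now=z_now,
            bmiz_rate_per_30d=rate,
        )
        return decision, alerts
    if rate is None:
        return None, alerts
    return (
        titrate(
            z_now,
            rate,
            threshold_z=cfg.maintenance_bmiz,
            excessive_loss_z=cfg.excessive_loss_z,
        ),
        alerts,
    )


def weekly_adherence_report(
    profiles: list[ChildProfile],
    weighins_by_child: dict[str, WeighInSeries],
    ref: GrowthReference,
    weeks: int,
    cfg: MonitorConfig = MonitorConfig(),
) -> dict:
    """JSON-serialisable monitoring report per child.

    Includes weekly weigh-in adherence over ``weeks`` 7-day bins from
    baseline, active safety alerts, and the titration decision; children
    with no usable weigh-ins are reported as 'insufficient data'.
    """
    report: dict = {}
    for p in profiles:
        series = weighins_by_child.get(p.child_id) or WeighInSeries(p.child_id, ())
        if not series.records:
            report[p.child_id] = {
                "status": "insufficient data",
                "weekly_adherence": 0.0,
                "alerts": [],
                "titration": None,
            }
            continue
        decision, alerts = evaluate_titration(p, series, ref, cfg=cfg)
        report[p.child_id] = {
            "status": "ok" if decision is not None else "insufficient data",
            "weekly_adherence": weekly_adherence(series, p.baseline.date, weeks),
            "alerts": [
                {
                    "kind": a.kind,
                    "window_start": a.window_start.isoformat(),
                    "window_end": a.window_end.isoformat(),
                    "magnitude": a.magnitude,
                }
                for a in alerts
            ],
            "titration": None
            if decision is None
            else {
                "action": decision.action,
                "rule_fired": decision.rule_fired,
                "bmiz_now": decision.bmiz_now,
                "bmiz_rate_per_30d": decision.bmiz_rate_per_30d,
            },
        }
    return report


def graph_series(zones: list[ZoneSpec], weigh_ins: WeighInSeries) -> GraphSeries:
    """Assemble the plottable weight-graph series in pounds.

    Zone bounds are step-constant: each weigh-in uses the latest zone whose
    effective date is on or before it.  Weigh-ins before the first zone are
    excluded with a warning.
    """
    if not zones:
        raise ValueError("at least one zone required")
    zones = sorted(zones, key=lambda z: z.effective_date)
    eff = [z.effective_date for z in zones]
    if len(set(eff)) != len(eff):
        raise ValueError("zones must have distinct effective dates")

    dates, w_lb, lo_lb, hi_lb = [], [], [], []
    dropped = 0
    for date, w in weigh_ins.records:
        active = None
        for z in zones:
            if z.effective_date <= date:
                active = z
            else:
                break
        if active is None:
            dropped += 1
            continue
        dates.append(date)
        w_lb.append(w / LB_TO_KG)
        lo_lb.append(active.lower_lb)
        hi_lb.append(active.upper_lb)
    if dropped:
        warnings.warn(
            f"{weigh_ins.child_id}: excluded {dropped} weigh-in(s) before the "
            "first zone's effective date",
            stacklevel=2,
        )
    return GraphSeries(
        child_id=weigh_ins.child_id,
        dates=tuple(dates),
        observed_weights_lb=tuple(w_lb),
        zone_lower_lb=tuple(lo_lb),
        zone_upper_lb=tuple(hi_lb),
    )


def plot_weight_graph(series: GraphSeries, ax=None):
    """Render the weight graph: observed weights against the shaded zone."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4.5))
    ax.fill_between(
        series.dates,
        series.zone_lower_lb,
        series.zone_upper_lb,
        step="post",
        alpha=0.25,
        color="tab:green",
        label="adherence zone",
    )
    ax.plot(series.dates, series.observed_weights_lb, "o-", color="tab:blue",
            label="weight")
    ax.set_xlabel("date")
    ax.set_ylabel("weight (lb)")
    ax.set_title(f"Weight graph — {series.child_id}")
    ax.legend(loc="best")
    ax.figure.autofmt_xdate()
    return ax
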