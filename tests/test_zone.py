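"""Adherence-zone construction, safety triggers, and titration rules."""

import datetime as dt
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pedizone.data_io import WeighInSeries
from pedizone.growth import LB_TO_KG, Anthropometry, lms_inverse
from pedizone.zone_monitor import (
    MonitorConfig,
    TitrationDecision,
    adjust_zone_for_height,
    bmiz_rate,
    build_zone,
    classify_weighin,
    evaluate_titration,
    graph_series,
    safety_check,
    titrate,
)

from conftest import BASE_DATE, child_at_z

LONG_TERM = MonitorConfig(mode="long_term")


def weighins_at_z(profile, flat_ref, day_z_pairs):
    """Weigh-ins whose BMIz (at constant height, age-flat reference) follows
    the given (day, z) schedule."""
    rec = flat_ref.lookup(profile.sex, 120.0)
    h2 = (profile.baseline.height_cm / 100.0) ** 2
    return WeighInSeries(
        profile.child_id,
        tuple(
            (BASE_DATE + dt.timedelta(days=day), lms_inverse(z, rec) * h2)
            for day, z in day_z_pairs
        ),
    )


class TestBuildZone:
    def test_high_percentile_band_centered_on_baseline(self, ref):
        child = child_at_z(ref, 1.4, weight_kg=40.0)  # ~92nd percentile
        zone = build_zone(child, ref)
        assert zone.lower_kg == pytest.approx(40.0 - 3 * LB_TO_KG, abs=1e-9)
        assert zone.upper_kg == pytest.approx(40.0 + 3 * LB_TO_KG, abs=1e-9)
        assert zone.loss_allowance_lb == 3.0

    def test_low_percentile_band_anchored_at_lower_bound(self, ref):
        child = child_at_z(ref, 0.5, weight_kg=30.0)  # ~69th percentile
        zone = build_zone(child, ref)
        assert zone.lower_kg == pytest.approx(30.0, abs=1e-12)
        assert zone.upper_kg == pytest.approx(30.0 + 6 * LB_TO_KG, abs=1e-9)
        assert zone.loss_allowance_lb == 0.0

    def test_target_bmiz_floors_at_maintenance_threshold(self, ref):
        high = build_zone(child_at_z(ref, 1.4, weight_kg=40.0), ref)
        low = build_zone(child_at_z(ref, 0.1, weight_kg=30.0), ref)
        assert high.target_bmiz == pytest.approx(1.4, abs=1e-9)
        assert low.target_bmiz == 0.25

    @given(z=st.floats(-0.5, 2.2), weight=st.floats(18.0, 90.0))
    @settings(max_examples=100, deadline=None)
    def test_width_always_six_pounds(self, ref, z, weight):
        zone = build_zone(child_at_z(ref, z, weight_kg=weight), ref)
        assert zone.upper_kg - zone.lower_kg == pytest.approx(
            6 * LB_TO_KG, abs=1e-9
        )
        assert zone.upper_kg - zone.lower_kg == pytest.approx(2.7215542, abs=1e-6)
        assert zone.lower_kg <= zone.anchor_weight_kg <= zone.upper_kg


class TestClassifyWeighin:
    def test_boundaries_inclusive(self, ref):
        zone = build_zone(child_at_z(ref, 1.4, weight_kg=40.0), ref)
        assert classify_weighin(zone, zone.lower_kg) == "in_zone"
        assert classify_weighin(zone, zone.upper_kg) == "in_zone"
        assert classify_weighin(zone, zone.anchor_weight_kg) == "in_zone"
        assert classify_weighin(zone, zone.upper_kg + 0.001) == "above"
        assert classify_weighin(zone, zone.lower_kg - 0.001) == "below"


class TestZoneAdjustment:
    def test_fixed_point_when_nothing_changes(self, flat_ref):
        child = child_at_z(flat_ref, 1.4, weight_kg=40.0)
        zone = build_zone(child, flat_ref)
        adjusted = adjust_zone_for_height(
            zone, child.baseline, child, flat_ref, force=True
        )
        assert adjusted.lower_kg == pytest.approx(zone.lower_kg, abs=1e-9)
        assert adjusted.upper_kg == pytest.approx(zone.upper_kg, abs=1e-9)
        assert adjusted.revision_index == 1

    def test_anchor_scales_with_height_squared_on_constant_median(self, flat_ref):
        # target z = 0 on an age-constant reference: anchor is M * (h/100)^2,
        # so growing 140 -> 145 cm multiplies the anchor by (1.45/1.40)^2
        child = child_at_z(flat_ref, 0.0, age_months=120.0)
        assert child.baseline.height_cm == 140.0
        zone = build_zone(child, flat_ref)
        # force target z = 0 (this child is exactly at the median)
        zone = zone.__class__(**{**zone.__dict__, "target_bmiz": 0.0})
        new_anthro = Anthropometry(
            date=BASE_DATE + dt.timedelta(days=183),
            height_cm=145.0,
            weight_kg=child.baseline.weight_kg,
        )
        adjusted = adjust_zone_for_height(zone, new_anthro, child, flat_ref, force=True)
        assert adjusted.anchor_weight_kg / zone.anchor_weight_kg == pytest.approx(
            (1.45 / 1.40) ** 2, abs=1e-9
        )

    def test_adjusted_anchor_sits_at_target_bmiz(self, ref):
        child = child_at_z(ref, 1.4, weight_kg=40.0)
        zone = build_zone(child, ref, LONG_TERM)
        new_anthro = Anthropometry(
            date=BASE_DATE + dt.timedelta(days=200), height_cm=142.0, weight_kg=40.0
        )
        adjusted = adjust_zone_for_height(zone, new_anthro, child, ref, LONG_TERM)
        check = Anthropometry(
            date=new_anthro.date,
            height_cm=new_anthro.height_cm,
            weight_kg=adjusted.anchor_weight_kg,
        )
        from pedizone.growth import bmiz

        assert bmiz(child, check, ref) == pytest.approx(zone.target_bmiz, abs=1e-6)

    def test_idempotent_at_fixed_height_age_target(self, ref):
        child = child_at_z(ref, 1.4, weight_kg=40.0)
        zone = build_zone(child, ref, LONG_TERM)
        anthro = Anthropometry(
            date=BASE_DATE + dt.timedelta(days=200), height_cm=142.0, weight_kg=40.0
        )
        once = adjust_zone_for_height(zone, anthro, child, ref, LONG_TERM)
        twice = adjust_zone_for_height(once, anthro, child, ref, LONG_TERM, force=True)
        assert twice.anchor_weight_kg == pytest.approx(once.anchor_weight_kg, abs=1e-12)
        assert twice.lower_kg == pytest.approx(once.lower_kg, abs=1e-12)

    def test_pilot_mode_requires_force(self, ref):
        child = child_at_z(ref, 1.4, weight_kg=40.0)
        zone = build_zone(child, ref)
        anthro = Anthropometry(
            date=BASE_DATE + dt.timedelta(days=200), height_cm=142.0, weight_kg=40.0
        )
        with pytest.raises(ValueError):
            adjust_zone_for_height(zone, anthro, child, ref)  # pilot_13wk default

    def test_long_term_mode_requires_interval(self, ref):
        child = child_at_z(ref, 1.4, weight_kg=40.0)
        zone = build_zone(child, ref, LONG_TERM)
        early = Anthropometry(
            date=BASE_DATE + dt.timedelta(days=30), height_cm=141.0, weight_kg=40.0
        )
        with pytest.raises(ValueError):
            adjust_zone_for_height(zone, early, child, ref, LONG_TERM)

    def test_height_decrease_warns_but_recomputes(self, ref):
        child = child_at_z(ref, 1.4, weight_kg=40.0)
        zone = build_zone(child, ref)
        shrunk = Anthropometry(
            date=BASE_DATE + dt.timedelta(days=200),
            height_cm=child.baseline.height_cm - 2.0,
            weight_kg=40.0,
        )
        with pytest.warns(UserWarning, match="height decreased"):
            adjusted = adjust_zone_for_height(zone, shrunk, child, ref, force=True)
        assert adjusted.revision_index == 1


class TestBMIzRate:
    def test_constant_weight_gives_zero(self, flat_ref):
        child = child_at_z(flat_ref, 1.0)
        series = weighins_at_z(child, flat_ref, [(0, 1.0), (15, 1.0), (30, 1.0)])
        assert bmiz_rate(child, series, flat_ref) == pytest.approx(0.0, abs=1e-12)

    def test_linear_scaling_to_window(self, flat_ref):
        # BMIz falls 0.1 in 15 days -> -0.2 per 30 days
        child = child_at_z(flat_ref, 1.0)
        series = weighins_at_z(child, flat_ref, [(0, 1.0), (15, 0.9)])
        assert bmiz_rate(child, series, flat_ref) == pytest.approx(-0.2, abs=1e-9)

    def test_insufficient_data_is_undefined_not_alert(self, flat_ref):
        child = child_at_z(flat_ref, 1.0)
        one = weighins_at_z(child, flat_ref, [(0, 1.0)])
        short = weighins_at_z(child, flat_ref, [(0, 1.0), (3, 0.9)])
        assert bmiz_rate(child, one, flat_ref) is None
        assert bmiz_rate(child, short, flat_ref) is None
        assert safety_check(child, one, flat_ref) == []

    def test_regression_estimator_matches_on_linear_series(self, flat_ref):
        child = child_at_z(flat_ref, 1.0)
        series = weighins_at_z(
            child, flat_ref, [(0, 1.0), (10, 0.95), (20, 0.90), (30, 0.85)]
        )
        endpoint = bmiz_rate(child, series, flat_ref, estimator="endpoint")
        slope = bmiz_rate(child, series, flat_ref, estimator="regression")
        assert endpoint == pytest.approx(-0.15, abs=1e-6)
        assert slope == pytest.approx(endpoint, abs=1e-6)

    def test_brute_force_recomputation_on_random_series(self, flat_ref):
        """Endpoint-rate oracle recomputed from raw weights with the
        closed-form z of the flat reference."""
        import numpy as np

        rng = np.random.default_rng(7)
        child = child_at_z(flat_ref, 1.0)
        h2 = (child.baseline.height_cm / 100.0) ** 2
        for _ in range(50):
            days = sorted(rng.choice(np.arange(0, 31), size=5, replace=False))
            if days[-1] - days[0] < 7:
                continue
            weights = rng.uniform(30.0, 45.0, size=5)
            series = WeighInSeries(
                child.child_id,
                tuple(
                    (BASE_DATE + dt.timedelta(days=int(d)), float(w))
                    for d, w in zip(days, weights)
                ),
            )

            def z_of(w):  # closed form: L=-1.5, M=17.4, S=0.12
                return (((w / h2) / 17.4) ** -1.5 - 1.0) / (-1.5 * 0.12)

            expected = (z_of(weights[-1]) - z_of(weights[0])) * 30 / (days[-1] - days[0])
            got = bmiz_rate(child, series, flat_ref, window_days=30)
            assert got == pytest.approx(expected, abs=1e-9)


class TestSafetyCheck:
    def test_flat_series_is_safe(self, flat_ref):
        child = child_at_z(flat_ref, 1.0)
        series = weighins_at_z(child, flat_ref, [(0, 1.0), (7, 1.0), (14, 1.0)])
        assert safety_check(child, series, flat_ref) == []

    def test_three_pounds_in_a_week_triggers_weekly_loss(self, flat_ref):
        child = child_at_z(flat_ref, 1.5, weight_kg=45.0)
        series = WeighInSeries(
            child.child_id,
            ((BASE_DATE, 45.0), (BASE_DATE + dt.timedelta(days=7), 45.0 - 3 * LB_TO_KG)),
        )
        kinds = {a.kind for a in safety_check(child, series, flat_ref)}
        assert "excessive_weekly_loss" in kinds

    def test_quarter_bmiz_in_a_month_triggers_bmiz_loss(self, flat_ref):
        child = child_at_z(flat_ref, 1.0)
        series = weighins_at_z(child, flat_ref, [(0, 1.0), (30, 0.75)])
        alerts = safety_check(child, series, flat_ref)
        assert any(a.kind == "excessive_bmiz_loss" for a in alerts)
        bmiz_alert = next(a for a in alerts if a.kind == "excessive_bmiz_loss")
        assert bmiz_alert.magnitude == pytest.approx(-0.25, abs=1e-9)

    def test_exactly_two_pounds_per_week_never_triggers(self, flat_ref):
        child = child_at_z(flat_ref, 1.8, weight_kg=60.0)
        records = [
            (BASE_DATE + dt.timedelta(days=7 * k), 60.0 - 2 * LB_TO_KG * k)
            for k in range(5)
        ]
        series = WeighInSeries(child.child_id, tuple(records))
        kinds = {a.kind for a in safety_check(child, series, flat_ref)}
        assert "excessive_weekly_loss" not in kinds

    def test_just_over_two_pounds_per_week_always_triggers(self, flat_ref):
        child = child_at_z(flat_ref, 1.8, weight_kg=60.0)
        records = [
            (BASE_DATE + dt.timedelta(days=7 * k), 60.0 - 2.01 * LB_TO_KG * k)
            for k in range(5)
        ]
        series = WeighInSeries(child.child_id, tuple(records))
        kinds = {a.kind for a in safety_check(child, series, flat_ref)}
        assert "excessive_weekly_loss" in kinds

    @given(extra=st.floats(0.01, 2.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_loss(self, flat_ref, extra):
        # if a series triggers, any series with pointwise larger losses does too
        child = child_at_z(flat_ref, 1.8, weight_kg=60.0)

        def series_with_weekly_loss(loss_lb):
            return WeighInSeries(
                child.child_id,
                tuple(
                    (BASE_DATE + dt.timedelta(days=7 * k), 60.0 - loss_lb * LB_TO_KG * k)
                    for k in range(4)
                ),
            )

        base_triggers = any(
            a.kind == "excessive_weekly_loss"
            for a in safety_check(child, series_with_weekly_loss(2.1), flat_ref)
        )
        worse_triggers = any(
            a.kind == "excessive_weekly_loss"
            for a in safety_check(child, series_with_weekly_loss(2.1 + extra), flat_ref)
        )
        assert base_triggers and worse_triggers


class TestTitration:
    @pytest.mark.parametrize(
        "z, rate, action, rule",
        [
            (1.0, -0.25, "increase", "excessive_loss"),
            (1.0, 0.10, "reduce", "gaining_above_threshold"),
            (0.20, 0.10, "maintain", "at_or_below_threshold"),
            (1.0, 0.00, "maintain", "maintenance_above_threshold"),
            (0.25, 0.10, "maintain", "at_or_below_threshold"),
            (0.26, 0.10, "reduce", "gaining_above_threshold"),
            (0.10, -0.30, "increase", "excessive_loss"),
        ],
    )
    def test_decision_table(self, z, rate, action, rule):
        d = titrate(z, rate)
        assert (d.action, d.rule_fired) == (action, rule)

    def test_grid_matches_brute_force_case_analysis(self):
        """Exhaustive 10^4-point grid against an independently written
        case analysis of the three published rules."""
        import numpy as np

        def oracle(z, rate):
            if rate < -0.2:
                return "increase"
            if z <= 0.25:
                return "maintain"
            if rate > 0:
                return "reduce"
            return "maintain"

        zs = np.linspace(-2.0, 3.0, 100)
        rates = np.linspace(-1.0, 1.0, 100)
        for z in zs:
            for rate in rates:
                assert titrate(float(z), float(rate)).action == oracle(z, rate)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            titrate(float("nan"), 0.0)

    def test_exactly_one_rule_fires(self):
        d = titrate(0.9, -0.1)
        assert d.rule_fired in {
            "excessive_loss",
            "at_or_below_threshold",
            "gaining_above_threshold",
            "maintenance_above_threshold",
        }

    def test_safety_alert_forces_increase(self, flat_ref):
        # crash weight loss: BMIz stable-ish but > 2 lb/week lost
        child = child_at_z(flat_ref, 2.0, weight_kg=60.0)
        series = WeighInSeries(
            child.child_id,
            tuple(
                (BASE_DATE + dt.timedelta(days=7 * k), 60.0 - 2.5 * LB_TO_KG * k)
                for k in range(4)
            ),
        )
        decision, alerts = evaluate_titration(child, series, flat_ref)
        assert alerts
        assert decision.action == "increase"

    def test_no_data_reports_undefined(self, flat_ref):
        child = child_at_z(flat_ref, 1.0)
        decision, alerts = evaluate_titration(
            child, WeighInSeries(child.child_id, ()), flat_ref
        )
        assert decision is None and alerts == []


class TestGraphSeries:
    def test_single_zone_three_points(self, ref):
        child = child_at_z(ref, 1.4, weight_kg=40.0)
        zone = build_zone(child, ref)
        series = WeighInSeries(
            child.child_id,
            tuple(
                (BASE_DATE + dt.timedelta(days=7 * k), 40.0 + 0.1 * k)
                for k in range(3)
            ),
        )
        gs = graph_series([zone], series)
        assert len(gs.dates) == 3
        assert len(set(gs.zone_lower_lb)) == 1
        assert gs.zone_lower_lb[0] == pytest.approx(zone.lower_kg / LB_TO_KG)
        assert gs.observed_weights_lb[0] == pytest.approx(40.0 / LB_TO_KG)

    def test_bounds_step_at_revision_date(self, ref):
        child = child_at_z(ref, 1.4, weight_kg=40.0)
        zone = build_zone(child, ref, LONG_TERM)
        new_anthro = Anthropometry(
            date=BASE_DATE + dt.timedelta(days=190), height_cm=143.0, weight_kg=40.0
        )
        revised = adjust_zone_for_height(zone, new_anthro, child, ref, LONG_TERM)
        series = WeighInSeries(
            child.child_id,
            (
                (BASE_DATE + dt.timedelta(days=100), 40.0),
                (BASE_DATE + dt.timedelta(days=189), 40.2),
                (BASE_DATE + dt.timedelta(days=190), 40.4),
                (BASE_DATE + dt.timedelta(days=250), 40.6),
            ),
        )
        gs = graph_series([zone, revised], series)
        assert gs.zone_lower_lb[0] == gs.zone_lower_lb[1] == pytest.approx(zone.lower_lb)
        assert gs.zone_lower_lb[2] == gs.zone_lower_lb[3] == pytest.approx(revised.lower_lb)

    def test_weighins_before_first_zone_excluded_with_warning(self, ref):
        child = child_at_z(ref, 1.4, weight_kg=40.0)
        zone = build_zone(child, ref)
        series = WeighInSeries(
            child.child_id,
            ((BASE_DATE - dt.timedelta(days=5), 40.0), (BASE_DATE, 40.0)),
        )
        with pytest.warns(UserWarning, match="excluded"):
            gs = graph_series([zone], series)
        assert len(gs.dates) == 1

    def test_json_export_round_trips(self, ref):
        import json

        child = child_at_z(ref, 1.4, weight_kg=40.0)
        zone = build_zone(child, ref)
        series = WeighInSeries(child.child_id, ((BASE_DATE, 40.0),))
        payload = json.loads(graph_series([zone], series).to_json())
        assert payload["dates"] == [BASE_DATE.isoformat()]
        assert payload["zone_upper_lb"][0] == pytest.approx(zone.upper_lb)
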