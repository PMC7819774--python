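"""Run configuration: YAML/JSON files plus programmatic overrides.

Recognised keys: ``pal``, ``deficit_kcal_d``, ``hb_coefficients``
("revised" | "original"), ``step_increment``, ``ramp_weeks``,
``traffic_light.green_max``, ``traffic_light.yellow_max``, ``mode``
("pilot_13wk" | "long_term"), and the monitor thresholds ``width_lb``,
``loss_allowance_lb``, ``maintenance_bmiz``, ``excessive_loss_z``,
``max_weekly_loss_lb``, ``rate_window_days``, ``rate_estimator``.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .goals import HB_ORIGINAL, HB_REVISED, TrafficLightConfig
from .zone_monitor import MonitorConfig

__all__ = ["ConfigError", "load_config", "monitor_config", "goals_config"]

_MONITOR_KEYS = {
    "width_lb",
    "loss_allowance_lb",
    "loss_allowance_pctile",
    "maintenance_bmiz",
    "excessive_loss_z",
    "max_weekly_loss_lb",
    "rate_window_days",
    "rate_estimator",
    "mode",
    "revision_interval_days",
}


class ConfigError(ValueError):
    """Invalid run configuration."""


def load_config(path=None) -> dict:
    """Load a YAML or JSON config file into a plain dict ({} if no path)."""
    if path is None:
        return {}
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            return json.loads(text) or {}
        return yaml.safe_load(text) or {}
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigError(f"unparseable config {path}: {exc}") from exc


def monitor_config(cfg: dict) -> MonitorConfig:
    kwargs = {k: v for k, v in cfg.items() if k in _MONITOR_KEYS}
    try:
        mc = MonitorConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    if mc.mode not in ("pilot_13wk", "long_term"):
        raise ConfigError(f"unknown mode {mc.mode!r}")
    if mc.width_lb <= 0 or mc.max_weekly_loss_lb <= 0 or mc.excessive_loss_z <= 0:
        raise ConfigError("monitor thresholds must be positive")
    return mc


def goals_config(cfg: dict) -> dict:
    """Normalise energy/step/traffic-light settings with defaults."""
    hb_name = cfg.get("hb_coefficients", "revised")
    try:
        hb = {"revised": HB_REVISED, "original": HB_ORIGINAL}[hb_name]
    except KeyError:
        raise ConfigError(f"hb_coefficients must be 'revised' or 'original', got {hb_name!r}")
    tl = cfg.get("traffic_light", {}) or {}
    try:
        tl_cfg = TrafficLightConfig(
            green_max_kcal=float(tl.get("green_max", 20.0)),
            yellow_max_kcal=float(tl.get("yellow_max", 50.0)),
        )
        out = {
            "pal": float(cfg.get("pal", 1.4)),
            "deficit_kcal_d": float(cfg.get("deficit_kcal_d", 250.0)),
            "hb_coefficients": hb,
            "step_increment": int(cfg.get("step_increment", 6000)),
            "ramp_weeks": int(cfg.get("ramp_weeks", 8)),
            "traffic_light": tl_cfg,
        }
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    if out["pal"] <= 0 or out["ramp_weeks"] < 1 or out["step_increment"] < 0:
        raise ConfigError("pal must be positive, ramp_weeks >= 1, step_increment >= 0")
    return out
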