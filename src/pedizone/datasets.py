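"""Bundled example survey-count tables and a generic survey-CSV reader.

Two small response-count tables from a pediatric telehealth
weight-management pilot program ship with the package:

* ``pilot_satisfaction_counts.csv`` — parent (6-point) and child (5-point)
  satisfaction items for 10 respondents, with the published Mean (SD) for
  each row.  Several child rows are internally inconsistent as published
  (counts summing past the respondent total; dispersion values that match
  neither the population nor the sample SD); they load with a validation
  warning and are excluded from reproduction checks.
* ``provider_feasibility_counts.csv`` — ten 4-point provider feasibility
  items (N=74; one item N=72 due to missing responses), with published
  Mean (SD) and, where stated, the top-2-box endorsement percentage.

The generic dialect read by :func:`read_survey_counts` is
``item_label,scale_size,c1,...,cK,nominal_n``.
"""

from __future__ import annotations

import warnings
from importlib import resources

import pandas as pd

from .survey_stats import LikertItem, LikertTable

__all__ = [
    "load_pilot_satisfaction",
    "load_provider_feasibility",
    "read_survey_counts",
    "table_from_frame",
]


def _data_path(name: str):
    return resources.files("pedizone.data").joinpath(name)


def _load(name: str) -> pd.DataFrame:
    with resources.as_file(_data_path(name)) as path:
        return pd.read_csv(path)


def load_pilot_satisfaction() -> pd.DataFrame:
    """Parent/child satisfaction counts with published Mean (SD).

    Columns: group, item_label, scale_size, c1..c6, nominal_n,
    mean_printed, sd_printed.
    """
    return _load("pilot_satisfaction_counts.csv")


def load_provider_feasibility() -> pd.DataFrame:
    """Provider feasibility counts (4-point) with published Mean (SD) and
    stated endorsement percentages."""
    return _load("provider_feasibility_counts.csv")


def table_from_frame(df: pd.DataFrame, respondents_nominal: int) -> LikertTable:
    """Build a LikertTable from a counts DataFrame (c1..cK columns)."""
    items = []
    for row in df.itertuples(index=False):
        k = int(row.scale_size)
        counts = tuple(int(getattr(row, f"c{j}")) for j in range(1, k + 1))
        nominal = int(row.nominal_n) if hasattr(row, "nominal_n") else None
        items.append(
            LikertItem(
                label=str(row.item_label),
                scale_size=k,
                counts=counts,
                nominal_n=nominal,
            )
        )
    table = LikertTable(items=tuple(items), respondents_nominal=respondents_nominal)
    for msg in table.validate():
        warnings.warn(msg, stacklevel=2)
    return table


def read_survey_counts(path) -> LikertTable:
    """Read a survey-counts CSV: ``item_label,scale_size,c1,...,cK,nominal_n``."""
    df = pd.read_csv(path)
    required = {"item_label", "scale_size", "nominal_n"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    nominal = int(df["nominal_n"].max())
    return table_from_frame(df, respondents_nominal=nominal)
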