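"""Readers and writers for monitoring CSVs, duplicate-measurement
reconciliation, and weekly weigh-in adherence.

File dialects (UTF-8, comma-separated, header required):

* ``weighins.csv``: ``child_id,date,weight_kg``
* ``steps.csv``:    ``child_id,date,steps``
* ``children.csv``: ``child_id,sex,birth_date,baseline_date,height_cm,weight_kg``
* LMS reference:    ``sex,agemos,L,M,S`` with sex coded 1=male, 2=female
  (``male``/``female`` strings also accepted)

Dates are ISO-8601 (YYYY-MM-DD).  Malformed rows are reported with their
line numbers in a single :class:`IngestionError`.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass

import pandas as pd

from .growth import (
    Anthropometry,
    ChildProfile,
    GrowthReference,
    LMSRecord,
    Sex,
)

__all__ = [
    "WeighInSeries",
    "StepSeries",
    "IngestionError",
    "ProtocolError",
    "reconcile_duplicates",
    "read_weighins",
    "read_steps",
    "read_lms",
    "read_children",
    "write_weighins",
    "write_steps",
    "weekly_adherence",
]

MAX_DAILY_STEPS = 100_000


class IngestionError(ValueError):
    """Raised when a monitoring CSV contains malformed rows.

    ``problems`` is a list of (line_number, message) pairs; line numbers
    are 1-based positions in the file, counting the header as line 1.
    """

    def __init__(self, path, problems: list[tuple[int, str]]):
        self.path = path
        self.problems = problems
        detail = "; ".join(f"line {ln}: {msg}" for ln, msg in problems)
        super().__init__(f"{path}: {detail}")


class ProtocolError(ValueError):
    """Measurement protocol violated (wrong number of duplicate measures)."""


@dataclass(frozen=True)
class WeighInSeries:
    """Time-ordered scale transmissions for one child: (date, weight_kg)."""

    child_id: str
    records: tuple[tuple[dt.date, float], ...]

    def __post_init__(self):
        dates = [d for d, _ in self.records]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("weigh-in dates must be strictly increasing")

    @property
    def dates(self) -> list[dt.date]:
        return [d for d, _ in self.records]

    @property
    def weights_kg(self) -> list[float]:
        return [w for _, w in self.records]

    def window(self, start: dt.date, end: dt.date) -> "WeighInSeries":
        """Records with start <= date <= end."""
        return WeighInSeries(
            self.child_id,
            tuple(r for r in self.records if start <= r[0] <= end),
        )


@dataclass(frozen=True)
class StepSeries:
    """Time-ordered daily step counts for one child: (date, steps)."""

    child_id: str
    records: tuple[tuple[dt.date, int], ...]

    def __post_init__(self):
        dates = [d for d, _ in self.records]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("step-log dates must be strictly increasing")


def reconcile_duplicates(
    m1: float, m2: float, m3: float | None = None, tolerance: float = 0.5
) -> float:
    """Combine duplicate anthropometric measurements per protocol.

    If the first two measures agree within ``tolerance`` units their mean is
    used and a third measure must not be present.  If they disagree by more
    than ``tolerance`` a third measure is required and the closest two of
    the three are averaged.  When the third measure is equidistant from both
    earlier ones, it is averaged with the second (later measurements are
    presumed more careful).
    """
    gap = abs(m1 - m2)
    if gap <= tolerance:
        if m3 is not None:
            raise ProtocolError(
                f"third measurement supplied but |m1-m2|={gap:g} <= {tolerance:g}"
            )
        return (m1 + m2) / 2.0
    if m3 is None:
        raise ProtocolError(
            f"|m1-m2|={gap:g} > {tolerance:g} requires a third measurement"
        )
    d13, d23 = abs(m1 - m3), abs(m2 - m3)
    if d13 < d23 and d13 < gap:
        pair = (m1, m3)
    elif d23 <= d13 and d23 < gap:
        # ties between d13 and d23 resolve toward the later measurement m2
        pair = (m2, m3)
    else:
        pair = (m1, m2)
    return (pair[0] + pair[1]) / 2.0


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV structure
        raise IngestionError(path, [(1, f"unreadable CSV: {exc}")]) from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise IngestionError(path, [(1, f"missing columns: {', '.join(missing)}")])
    return df


def _parse_date(text: str) -> dt.date:
    return dt.date.fromisoformat(text.strip())


def read_weighins(
    path, child_id: str | None = None, same_day: str = "earliest"
) -> WeighInSeries | dict[str, WeighInSeries]:
    """Read a wireless-scale export (``child_id,date,weight_kg``).

    Rows are validated (ISO dates, weight within (5, 300) kg) and sorted.
    Multiple same-day transmissions are collapsed — by default the earliest
    row in file order is kept (morning-weighing protocol), ``same_day='mean'``
    averages them — with a warning.  Returns a single series when
    ``child_id`` is given, else a dict keyed by child id.
    """
    if same_day not in ("earliest", "mean"):
        raise ValueError("same_day must be 'earliest' or 'mean'")
    df = _read_csv(path, ["child_id", "date", "weight_kg"])
    problems: list[tuple[int, str]] = []
    rows: dict[str, list[tuple[dt.date, float]]] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            date = _parse_date(row.date)
            weight = float(row.weight_kg)
            if not (5.0 < weight < 300.0):
                raise ValueError(f"weight_kg {weight} outside (5, 300)")
        except ValueError as exc:
            problems.append((line, str(exc)))
            continue
        rows.setdefault(str(row.child_id), []).append((date, weight))
    if problems:
        raise IngestionError(path, problems)

    out: dict[str, WeighInSeries] = {}
    for cid, recs in rows.items():
        by_date: dict[dt.date, list[float]] = {}
        order: list[dt.date] = []
        for date, w in recs:
            if date not in by_date:
                order.append(date)
            by_date.setdefault(date, []).append(w)
        dupes = [d for d in order if len(by_date[d]) > 1]
        if dupes:
            warnings.warn(
                f"{cid}: collapsed same-day duplicate weigh-ins on "
                f"{', '.join(d.isoformat() for d in dupes)} ({same_day})",
                stacklevel=2,
            )
        collapsed = []
        for date in sorted(by_date):
            ws = by_date[date]
            collapsed.append(
                (date, ws[0] if same_day == "earliest" else sum(ws) / len(ws))
            )
        out[cid] = WeighInSeries(cid, tuple(collapsed))
    if child_id is not None:
        return out.get(child_id, WeighInSeries(child_id, ()))
    return out


def read_steps(
    path, child_id: str | None = None
) -> StepSeries | dict[str, StepSeries]:
    """Read a pedometer log (``child_id,date,steps``); gaps stay missing."""
    df = _read_csv(path, ["child_id", "date", "steps"])
    problems: list[tuple[int, str]] = []
    rows: dict[str, list[tuple[dt.date, int]]] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        try:
            date = _parse_date(row.date)
            steps = int(row.steps)
            if steps < 0:
                raise ValueError(f"steps {steps} is negative")
            if steps >= MAX_DAILY_STEPS:
                raise ValueError(f"steps {steps} >= {MAX_DAILY_STEPS}")
        except ValueError as exc:
            problems.append((line, str(exc)))
            continue
        rows.setdefault(str(row.child_id), []).append((date, steps))
    if problems:
        raise IngestionError(path, problems)
    out = {
        cid: StepSeries(cid, tuple(sorted(set(recs))))
        for cid, recs in rows.items()
    }
    for cid, series in out.items():
        if len({d for d, _ in series.records}) != len(series.records):
            raise IngestionError(path, [(1, f"{cid}: conflicting same-day step rows")])
    if child_id is not None:
        return out.get(child_id, StepSeries(child_id, ()))
    return out


def read_lms(path) -> GrowthReference:
    """Read an LMS reference CSV (``sex,agemos,L,M,S``)."""
    df = _read_csv(path, ["sex", "agemos", "L", "M", "S"])
    problems: list[tuple[int, str]] = []
    records: dict[Sex, list[LMSRecord]] = {Sex.MALE: [], Sex.FEMALE: []}
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        try:
            rec = LMSRecord(
                sex=Sex.coerce(row.sex),
                age_months=float(row.agemos),
                L=float(row.L),
                M=float(row.M),
                S=float(row.S),
            )
        except ValueError as exc:
            problems.append((line, str(exc)))
            continue
        records[rec.sex].append(rec)
    if problems:
        raise IngestionError(path, problems)
    for sex in list(records):
        records[sex] = sorted(records[sex], key=lambda r: r.age_months)
        if not records[sex]:
            del records[sex]
    try:
        return GrowthReference(records)
    except ValueError as exc:
        raise IngestionError(path, [(1, str(exc))]) from exc


def read_children(path) -> list[ChildProfile]:
    """Read child profiles (``children.csv`` dialect)."""
    df = _read_csv(
        path,
        ["child_id", "sex", "birth_date", "baseline_date", "height_cm", "weight_kg"],
    )
    problems: list[tuple[int, str]] = []
    profiles: list[ChildProfile] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        try:
            baseline = Anthropometry(
                date=_parse_date(row.baseline_date),
                height_cm=float(row.height_cm),
                weight_kg=float(row.weight_kg),
            )
            profiles.append(
                ChildProfile(
                    child_id=str(row.child_id),
                    sex=Sex.coerce(row.sex),
                    birth_date=_parse_date(row.birth_date),
                    baseline=baseline,
                )
            )
        except ValueError as exc:
            problems.append((line, str(exc)))
    if problems:
        raise IngestionError(path, problems)
    return profiles


def write_weighins(path, series_by_child: dict[str, WeighInSeries]) -> None:
    rows = [
        {"child_id": cid, "date": d.isoformat(), "weight_kg": repr(w)}
        for cid, s in series_by_child.items()
        for d, w in s.records
    ]
    pd.DataFrame(rows, columns=["child_id", "date", "weight_kg"]).to_csv(
        path, index=False
    )


def write_steps(path, series_by_child: dict[str, StepSeries]) -> None:
    rows = [
        {"child_id": cid, "date": d.isoformat(), "steps": n}
        for cid, s in series_by_child.items()
        for d, n in s.records
    ]
    pd.DataFrame(rows, columns=["child_id", "date", "steps"]).to_csv(path, index=False)


def weekly_adherence(series: WeighInSeries, start: dt.date, weeks: int) -> float:
    """Fraction of consecutive 7-day bins from ``start`` with >= 1 weigh-in.

    Bins are half-open: [start + 7k, start + 7(k+1)).
    """
    if weeks < 1:
        raise ValueError("weeks must be >= 1")
    hit = [False] * weeks
    for date, _ in series.records:
        k = (date - start).days // 7
        if 0 <= k < weeks:
            hit[k] = True
    return sum(hit) / weeks
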