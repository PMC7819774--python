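"""Likert-scale survey summaries and paired pre/post analysis.

Descriptive statistics for per-item response-count tables on K-point Likert
scales: item mean, population SD (denominator n — the convention the
bundled example tables were published with), and top-2-box endorsement
(Agree + Strongly Agree on a 4-point scale).  The paired t-test for
pre/post anthropometric change is provided in both raw-pairs and
summary-statistics form; the descriptive tables use the population SD while
the t statistic uses the sample SD of the differences, and both conventions
are deliberate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LikertItem",
    "LikertTable",
    "PairedSummary",
    "likert_summary",
    "endorsement",
    "paired_t_from_summary",
    "paired_t_from_pairs",
    "round_half_up",
    "summarize_table",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero toward +inf)."""
    factor = 10.0**ndigits
    return math.floor(x * factor + 0.5) / factor


@dataclass(frozen=True)
class LikertItem:
    """One survey item: label, K-point scale, per-level response counts."""

    label: str
    scale_size: int
    counts: tuple[int, ...]
    #: stated respondent N for this item; None falls back to the table's
    #: nominal N (items with missing responses can state their own).
    nominal_n: int | None = None

    def __post_init__(self):
        if self.scale_size not in (4, 5, 6):
            raise ValueError("scale_size must be 4, 5, or 6")
        if len(self.counts) != self.scale_size:
            raise ValueError("counts length must equal scale_size")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return sum(self.counts)


@dataclass(frozen=True)
class LikertTable:
    """A set of Likert items sharing a nominal respondent count."""

    items: tuple[LikertItem, ...]
    respondents_nominal: int

    def __post_init__(self):
        if self.respondents_nominal < 1:
            raise ValueError("respondents_nominal must be positive")

    def validate(self) -> list[str]:
        """Return warnings for items whose counts exceed the nominal N."""
        msgs = []
        for item in self.items:
            nominal = item.nominal_n or self.respondents_nominal
            if item.n > nominal:
                msgs.append(
                    f"{item.label!r}: counts sum to {item.n} > nominal "
                    f"N={nominal} (inconsistent row)"
                )
        return msgs


@dataclass(frozen=True)
class PairedSummary:
    """Summary statistics of paired differences (post − pre)."""

    mean_diff: float
    sd_diff: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.sd_diff <= 0:
            raise ValueError("sd_diff must be positive")


def likert_summary(counts) -> tuple[int, float, float]:
    """(n, mean, population SD) of a Likert item from per-level counts.

    Levels are 1..K.  SD uses the population denominator n (the published
    descriptive convention), not n−1.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or np.any(counts < 0):
        raise ValueError("counts must be a 1-D non-negative vector")
    n = counts.sum()
    if n < 1:
        raise ValueError("at least one response required")
    levels = np.arange(1, counts.size + 1, dtype=float)
    mean = float((levels * counts).sum() / n)
    var = float((counts * (levels - mean) ** 2).sum() / n)
    return int(n), mean, math.sqrt(var)


def endorsement(counts_4level, denominator: int) -> tuple[int, int]:
    """Top-2-box endorsement on a 4-point agreement scale.

    Returns (count, percent): count is Agree + Strongly Agree (levels 3 and
    4), percent is 100·count/denominator rounded half-up to an integer.
    The denominator is the stated respondent N, which may exceed the item's
    own response total when responses are missing.
    """
    counts = tuple(int(c) for c in counts_4level)
    if len(counts) != 4 or any(c < 0 for c in counts):
        raise ValueError("need 4 non-negative counts")
    if denominator < 1:
        raise ValueError("denominator must be positive")
    if sum(counts) > denominator:
        raise ValueError("counts exceed denominator")
    count = counts[2] + counts[3]
    percent = int(round_half_up(100.0 * count / denominator))
    return count, percent


def paired_t_from_summary(s: PairedSummary) -> tuple[float, int, float]:
    """Paired t-test from (mean, sample SD, n) of the differences.

    Returns (t, df, two-sided p).  t = mean / (sd/√n), df = n − 1.
    """
    t = s.mean_diff / (s.sd_diff / math.sqrt(s.n))
    df = s.n - 1
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return t, df, p


def paired_t_from_pairs(pre, post) -> tuple[float, int, float, float, float]:
    """Paired t-test from raw pre/post vectors.

    Returns (t, df, two-sided p, mean_diff, sd_diff) where the difference is
    post − pre and sd_diff is the sample SD (denominator n − 1).  A zero
    sd_diff is degenerate and raises.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be 1-D vectors of equal length")
    if pre.size < 2:
        raise ValueError("need at least 2 pairs")
    d = post - pre
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    if sd_diff == 0.0:
        raise ValueError("zero variance of differences (degenerate)")
    t, df, p = paired_t_from_summary(PairedSummary(mean_diff, sd_diff, pre.size))
    return t, df, p, mean_diff, sd_diff


def summarize_table(table: LikertTable) -> pd.DataFrame:
    """Per-item summary DataFrame: n, mean, population SD, and (for 4-point
    items) top-2-box endorsement against the nominal N."""
    rows = []
    for item in table.items:
        n, mean, sd = likert_summary(item.counts)
        row = {
            "item": item.label,
            "scale_size": item.scale_size,
            "n": n,
            "mean": mean,
            "sd": sd,
            "mean_1dp": round_half_up(mean, 1),
            "sd_1dp": round_half_up(sd, 1),
        }
        if item.scale_size == 4:
            count, pct = endorsement(
                item.counts, item.nominal_n or table.respondents_nominal
            )
            row["endorse_count"] = count
            row["endorse_pct"] = pct
        rows.append(row)
    return pd.DataFrame(rows)
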