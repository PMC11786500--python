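"""XCI skewing statistic, four-category classification and descriptive summaries.

The per-position skewing percentage is

    skew = 100 * max(X1, X2) / (X1 + X2)

where X1/X2 are the UMI-collapsed counts of the two phased alleles. The
value lies in [50, 100] and is classified into four categories forming a
partition of that range:

    R   relatively random        [50, 70)
    S   skewing                  [70, 80)
    SS  severe skewing           [80, 90)
    E   extreme severe skewing   [90, 100]

Reported category percentages are rounded half-up to one decimal, matching
the convention of the descriptive tables this module emulates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .aggregate import PositionSummary

__all__ = [
    "CATEGORIES",
    "CATEGORY_LABELS",
    "SkewingCall",
    "CategoryDistribution",
    "DescriptiveSummary",
    "skew_percent",
    "classify_skew",
    "make_skewing_calls",
    "category_distribution",
    "describe",
    "describe_summaries",
    "calls_to_frame",
]

CATEGORIES: tuple[str, ...] = ("R", "S", "SS", "E")
CATEGORY_LABELS: dict[str, str] = {
    "R": "relatively random",
    "S": "skewing",
    "SS": "severe skewing",
    "E": "extreme severe skewing",
}
# lower bin edges; last bin closed at 100
_EDGES: tuple[tuple[str, float, float], ...] = (
    ("R", 50.0, 70.0),
    ("S", 70.0, 80.0),
    ("SS", 80.0, 90.0),
    ("E", 90.0, 100.0),
)


def skew_percent(x1: int, x2: int) -> float:
    """Skewing percentage 100*max(x1,x2)/(x1+x2); symmetric, in [50, 100]."""
    if x1 < 0 or x2 < 0:
        raise ValueError("allele counts must be non-negative")
    total = x1 + x2
    if total == 0:
        raise ValueError("skew_percent undefined for x1 + x2 == 0")
    return 100.0 * max(x1, x2) / total


def classify_skew(skew_pct: float) -> str:
    """Map a skew percentage in [50, 100] to its category code."""
    if not 50.0 <= skew_pct <= 100.0:
        raise ValueError(f"skew percentage {skew_pct} outside [50, 100]")
    for code, lo, hi in _EDGES:
        if lo <= skew_pct < hi:
            return code
    return "E"  # skew_pct == 100.0


@dataclass(frozen=True, slots=True)
class SkewingCall:
    """Skew percentage and category for one position passing the funnel."""

    pos: int
    x1: int
    x2: int
    skew_pct: float
    category: str


def make_skewing_calls(summaries: Sequence[PositionSummary]) -> list[SkewingCall]:
    """Compute skew percentage and category for each filtered position."""
    calls = []
    for s in summaries:
        pct = skew_percent(s.x1, s.x2)
        calls.append(SkewingCall(s.pos, s.x1, s.x2, pct, classify_skew(pct)))
    return calls


def _round_half_up(value: Decimal, decimals: int = 1) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(value.quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CategoryDistribution:
    """Category counts with half-up one-decimal percentages.

    ``percentages`` is empty when ``n_total`` is zero (flagged by
    ``undefined``); the aggregate properties report the share of positions
    at or above a given severity, rounded from the exact count ratio rather
    than from the per-category rounded values.
    """

    counts: dict[str, int]
    percentages: dict[str, float]
    n_total: int

    @property
    def undefined(self) -> bool:
        return self.n_total == 0

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "CategoryDistribution":
        full = {c: int(counts.get(c, 0)) for c in CATEGORIES}
        if any(v < 0 for v in full.values()):
            raise ValueError("category counts must be non-negative")
        n = sum(full.values())
        if n == 0:
            return cls(full, {}, 0)
        pct = {
            c: _round_half_up(Decimal(v) * 100 / Decimal(n))
            for c, v in full.items()
        }
        return cls(full, pct, n)

    def _pct_at_or_above(self, code: str) -> float:
        if self.undefined:
            raise ValueError("percentages undefined for an empty distribution")
        idx = CATEGORIES.index(code)
        count = sum(self.counts[c] for c in CATEGORIES[idx:])
        return _round_half_up(Decimal(count) * 100 / Decimal(self.n_total))

    @property
    def pct_skewing_or_higher(self) -> float:
        """Share of positions in S, SS or E (skew >= 70%)."""
        return self._pct_at_or_above("S")

    @property
    def pct_severe_or_higher(self) -> float:
        """Share of positions in SS or E (skew >= 80%)."""
        return self._pct_at_or_above("SS")

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "counts": dict(self.counts),
            "percentages": dict(self.percentages),
            "pct_skewing_or_higher": None if self.undefined else self.pct_skewing_or_higher,
            "pct_severe_or_higher": None if self.undefined else self.pct_severe_or_higher,
        }


def category_distribution(calls: Sequence[SkewingCall]) -> CategoryDistribution:
    """Tally calls per category and derive the rounded percentage distribution."""
    counts = {c: 0 for c in CATEGORIES}
    for call in calls:
        counts[call.category] += 1
    return CategoryDistribution.from_counts(counts)


@dataclass(frozen=True, slots=True)
class DescriptiveSummary:
    n: int
    minimum: float
    maximum: float
    mean: float
    sd: float


def describe(values: Sequence[float], ddof: int = 1) -> DescriptiveSummary:
    """Min/max/mean/SD of a non-empty vector (sample SD by default)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("describe requires a non-empty input")
    sd = float(np.std(arr, ddof=ddof)) if arr.size > ddof else 0.0
    return DescriptiveSummary(
        n=int(arr.size),
        minimum=float(arr.min()),
        maximum=float(arr.max()),
        mean=float(arr.mean()),
        sd=sd,
    )


def describe_summaries(
    summaries: Sequence[PositionSummary], ddof: int = 1
) -> pd.DataFrame:
    """Descriptive table over filtered positions, one row per quantity.

    Rows follow the conventional order X1, X2, %, barcoding frequency,
    number of barcodes.
    """
    if not summaries:
        raise ValueError("describe_summaries requires a non-empty input")
    rows = {
        "X1": [s.x1 for s in summaries],
        "X2": [s.x2 for s in summaries],
        "%": [skew_percent(s.x1, s.x2) for s in summaries],
        "Barcoding frequency": [s.barcoding_frequency for s in summaries],
        "Number of barcode": [s.n_barcodes for s in summaries],
    }
    table = []
    for name, vals in rows.items():
        d = describe(vals, ddof=ddof)
        table.append(
            {
                "quantity": name,
                "n": d.n,
                "minimum": d.minimum,
                "maximum": d.maximum,
                "mean": d.mean,
                "sd": d.sd,
            }
        )
    return pd.DataFrame(table)


def calls_to_frame(calls: Sequence[SkewingCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pos": [c.pos for c in calls],
            "x1": [c.x1 for c in calls],
            "x2": [c.x2 for c in calls],
            "skew_pct": [c.skew_pct for c in calls],
            "category": [c.category for c in calls],
        }
    )
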