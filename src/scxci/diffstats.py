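"""Per-SNP comparison of allelic skew between two samples.

At each position present in both samples' filtered sets, the UMI-collapsed
allele counts form a 2x2 table with rows (control, case). Because phased
haplotype labels are arbitrary per sample, the default column convention is
each sample's own (major, minor) counts, so the table contrasts the
*magnitude* of skew rather than a haplotype identity that does not exist
across unrelated individuals. On such a table the module computes:

* a pooled two-proportion Z test with two-sided normal p-value;
* Pearson's chi-square without continuity correction (identically Z^2);
* the Haldane-corrected Woolf odds ratio: 1/2 is added to every cell, and
  the Woolf standard error of log OR, sqrt(sum of reciprocals of corrected
  cells), gives a Wald confidence interval on the log scale — finite even
  for tables with empty cells;
* Bonferroni, Hochberg, Hommel and Benjamini-Hochberg FDR adjustments over
  the family of all shared positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .aggregate import PositionSummary
from .skewing import skew_percent

__all__ = [
    "ContingencyTable2x2",
    "SnpComparison",
    "ADJUST_METHODS",
    "build_table",
    "two_proportion_z",
    "chi_square_2x2",
    "haldane_woolf_or",
    "adjust_pvalues",
    "compare_samples",
    "direction_tally",
    "comparisons_to_frame",
]

Orientation = Literal["major_minor", "haplotype_labels"]

ADJUST_METHODS = ("bonferroni", "hochberg", "hommel", "fdr")
_SM_METHOD = {
    "bonferroni": "bonferroni",
    "hochberg": "simes-hochberg",
    "hommel": "hommel",
    "fdr": "fdr_bh",
    "fdr_by": "fdr_by",
}


@dataclass(frozen=True, slots=True)
class ContingencyTable2x2:
    """Counts a,b (row 1: control) and c,d (row 2: case), columns (major, minor)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def rows(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return (self.a, self.b), (self.c, self.d)

    def swapped_rows(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class SnpComparison:
    """All per-position comparison statistics for one shared SNP."""

    pos: int
    table: ContingencyTable2x2
    z: float
    p_z: float
    chi2: float
    p_chi2: float
    p_adj: dict[str, float]
    or_value: float
    ci_low: float
    ci_high: float
    direction: str  # case_greater | case_less | equal (by skew percentage)


def _major_minor(x1: int, x2: int) -> tuple[int, int]:
    # tie (x1 == x2) keeps the (x1, x2) order
    return (x1, x2) if x1 >= x2 else (x2, x1)


def build_table(
    control: PositionSummary,
    case: PositionSummary,
    orientation: Orientation = "major_minor",
) -> ContingencyTable2x2:
    """Form the 2x2 table for one position shared by both samples."""
    if control.pos != case.pos:
        raise ValueError(f"position mismatch: {control.pos} vs {case.pos}")
    if control.x1 + control.x2 == 0 or case.x1 + case.x2 == 0:
        raise ValueError("zero allele total in one sample")
    if orientation == "major_minor":
        a, b = _major_minor(control.x1, control.x2)
        c, d = _major_minor(case.x1, case.x2)
    elif orientation == "haplotype_labels":
        a, b, c, d = control.x1, control.x2, case.x1, case.x2
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return ContingencyTable2x2(a, b, c, d)


def two_proportion_z(t: ContingencyTable2x2) -> tuple[float, float]:
    """Pooled two-proportion Z statistic and two-sided normal p-value.

    Degenerate tables (pooled proportion 0 or 1, i.e. no variation) return
    (0.0, 1.0).
    """
    n1, n2 = t.a + t.b, t.c + t.d
    if n1 == 0 or n2 == 0:
        raise ValueError("both row sums must be positive")
    p1, p2 = t.a / n1, t.c / n2
    pooled = (t.a + t.c) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return 0.0, 1.0
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (p1 - p2) / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return z, min(p, 1.0)


def chi_square_2x2(t: ContingencyTable2x2) -> tuple[float, float]:
    """Pearson chi-square (df=1, no Yates correction) on a 2x2 table."""
    obs = np.array(t.rows, dtype=float)
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("chi-square requires positive row and column margins")
    chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)
    return float(chi2), float(p)


def haldane_woolf_or(
    t: ContingencyTable2x2, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Haldane-corrected Woolf odds ratio with a (1-alpha) confidence interval.

    OR = ((a+1/2)(d+1/2)) / ((b+1/2)(c+1/2)); SE(ln OR) is the square root
    of the sum of reciprocals of the corrected cells. Finite and positive
    for any non-negative table.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    a, b, c, d = (x + 0.5 for x in (t.a, t.b, t.c, t.d))
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    zcrit = stats.norm.ppf(1.0 - alpha / 2.0)
    return (
        math.exp(log_or),
        math.exp(log_or - zcrit * se),
        math.exp(log_or + zcrit * se),
    )


def adjust_pvalues(pvalues: Sequence[float], method: str) -> list[float]:
    """Multiplicity-adjusted p-values, same order as the input.

    ``method`` is one of bonferroni, hochberg, hommel, fdr (Benjamini-
    Hochberg step-up) or fdr_by (Benjamini-Yekutieli).
    """
    arr = np.asarray(pvalues, dtype=float)
    if arr.size == 0:
        return []
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if method not in _SM_METHOD:
        raise ValueError(f"unknown adjustment method {method!r}")
    _, adj, _, _ = multipletests(arr, alpha=0.05, method=_SM_METHOD[method])
    return [float(p) for p in adj]


def _direction(control: PositionSummary, case: PositionSummary) -> str:
    s_control = skew_percent(control.x1, control.x2)
    s_case = skew_percent(case.x1, case.x2)
    if math.isclose(s_case, s_control, rel_tol=0.0, abs_tol=1e-9):
        return "equal"
    return "case_greater" if s_case > s_control else "case_less"


def compare_samples(
    control: Sequence[PositionSummary],
    case: Sequence[PositionSummary],
    orientation: Orientation = "major_minor",
    alpha: float = 0.05,
) -> list[SnpComparison]:
    """Compare skew at every position present in both filtered sets.

    Adjusted p-values are computed once over the whole family of shared
    positions (from the Z-test p-values; the chi-square p is identical by
    the Z^2 identity). Tables without variation (a zero column margin)
    receive chi2 = 0, p = 1, mirroring the degenerate Z convention.
    Returns an empty list when no positions are shared.
    """
    control_by_pos = {s.pos: s for s in control}
    case_by_pos = {s.pos: s for s in case}
    shared = sorted(set(control_by_pos) & set(case_by_pos))
    if not shared:
        return []

    partial = []
    for pos in shared:
        nf, gd = control_by_pos[pos], case_by_pos[pos]
        t = build_table(nf, gd, orientation=orientation)
        z, p_z = two_proportion_z(t)
        try:
            chi2, p_chi2 = chi_square_2x2(t)
        except ValueError:
            chi2, p_chi2 = 0.0, 1.0
        or_value, lo, hi = haldane_woolf_or(t, alpha=alpha)
        partial.append(
            (pos, t, z, p_z, chi2, p_chi2, or_value, lo, hi, _direction(nf, gd))
        )

    raw = [p[3] for p in partial]
    adjusted = {m: adjust_pvalues(raw, m) for m in ADJUST_METHODS}
    return [
        SnpComparison(
            pos=pos,
            table=t,
            z=z,
            p_z=p_z,
            chi2=chi2,
            p_chi2=p_chi2,
            p_adj={m: adjusted[m][i] for m in ADJUST_METHODS},
            or_value=or_value,
            ci_low=lo,
            ci_high=hi,
            direction=direction,
        )
        for i, (pos, t, z, p_z, chi2, p_chi2, or_value, lo, hi, direction) in enumerate(
            partial
        )
    ]


def direction_tally(comparisons: Sequence[SnpComparison]) -> dict[str, int]:
    """Counts of case_greater / case_less / equal; sums to len(comparisons)."""
    tally = {"case_greater": 0, "case_less": 0, "equal": 0}
    for c in comparisons:
        tally[c.direction] += 1
    return tally


def comparisons_to_frame(comparisons: Sequence[SnpComparison]) -> pd.DataFrame:
    cols = {
        "pos": [c.pos for c in comparisons],
        "a": [c.table.a for c in comparisons],
        "b": [c.table.b for c in comparisons],
        "c": [c.table.c for c in comparisons],
        "d": [c.table.d for c in comparisons],
        "z": [c.z for c in comparisons],
        "p_z": [c.p_z for c in comparisons],
        "chi2": [c.chi2 for c in comparisons],
        "p_chi2": [c.p_chi2 for c in comparisons],
    }
    for m in ADJUST_METHODS:
        cols[f"p_{m}"] = [c.p_adj[m] for c in comparisons]
    cols.update(
        {
            "odds_ratio": [c.or_value for c in comparisons],
            "ci_low": [c.ci_low for c in comparisons],
            "ci_high": [c.ci_high for c in comparisons],
            "direction": [c.direction for c in comparisons],
        }
    )
    return pd.DataFrame(cols)
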