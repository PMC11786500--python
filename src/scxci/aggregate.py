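"""UMI collapsing and per-position allele aggregation.

Three layers of counting are kept distinct, reflecting the read > molecule >
cell hierarchy of droplet scRNA-seq:

* **barcoding frequency** — the raw read count at a position, over all cells;
* **X1 / X2** — UMI-collapsed molecule counts supporting each phased allele
  (a UMI group whose reads disagree on the haplotype is discarded as a PCR
  or phasing artefact, but its reads still count toward the frequency);
* **number of barcodes** — distinct cells observed at the position.

The skewing filter funnel retains positions with barcoding frequency in
[10, 1000], 3–30 barcodes, and at least 3 UMI-collapsed counts on *both*
alleles; every bound is inclusive.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import pandas as pd

from .phased_io import PhasedReadRecord

__all__ = [
    "UmiObservation",
    "PositionSummary",
    "FilterThresholds",
    "CollapseResult",
    "FunnelReport",
    "collapse_umis",
    "summarize_positions",
    "filter_for_skewing",
    "funnel_report",
    "summaries_to_frame",
]


@dataclass(frozen=True, slots=True)
class UmiObservation:
    """One UMI-collapsed molecule: a (pos, cell, UMI) group with a unanimous haplotype."""

    pos: int
    cell_barcode: str
    umi: str
    haplotype: str
    read_support: int

    def __post_init__(self) -> None:
        if self.read_support < 1:
            raise ValueError("read_support must be >= 1")


@dataclass(slots=True)
class PositionSummary:
    """Per-position aggregate of allele support, coverage and cell breadth.

    ``per_barcode`` maps each observed cell barcode to its (x1, x2) UMI
    counts; barcodes whose only UMIs were haplotype-conflicted appear with
    (0, 0).
    """

    pos: int
    x1: int
    x2: int
    barcoding_frequency: int
    n_barcodes: int
    per_barcode: dict[str, tuple[int, int]] = field(default_factory=dict)

    def validate(self) -> None:
        if min(self.x1, self.x2, self.barcoding_frequency, self.n_barcodes) < 0:
            raise ValueError("all counts must be non-negative")
        if self.x1 + self.x2 > self.barcoding_frequency:
            raise ValueError("x1 + x2 cannot exceed barcoding_frequency")
        if self.n_barcodes != len(self.per_barcode):
            raise ValueError("n_barcodes inconsistent with per_barcode")
        if self.x1 != sum(v[0] for v in self.per_barcode.values()):
            raise ValueError("x1 inconsistent with per_barcode")
        if self.x2 != sum(v[1] for v in self.per_barcode.values()):
            raise ValueError("x2 inconsistent with per_barcode")


@dataclass(frozen=True, slots=True)
class FilterThresholds:
    """Inclusive bounds of the position filter funnel."""

    freq_min: int = 10
    freq_max: int = 1000
    barcode_min: int = 3
    barcode_max: int = 30
    allele_min: int = 3

    def __post_init__(self) -> None:
        if self.freq_min > self.freq_max:
            raise ValueError("freq_min > freq_max")
        if self.barcode_min > self.barcode_max:
            raise ValueError("barcode_min > barcode_max")
        if self.allele_min < 1:
            raise ValueError("allele_min must be >= 1")


class CollapseResult(NamedTuple):
    observations: list[UmiObservation]
    n_conflicts: int


@dataclass(slots=True)
class FunnelReport:
    """The four funnel tallies: reads, barcodes, candidate and retained positions."""

    total_reads: int
    n_barcodes: int
    candidate_positions: int
    retained_positions: int

    def to_dict(self) -> dict[str, int]:
        return {
            "total_reads": self.total_reads,
            "n_barcodes": self.n_barcodes,
            "candidate_positions": self.candidate_positions,
            "retained_positions": self.retained_positions,
        }


def _group_reads(
    records: Iterable[PhasedReadRecord],
) -> dict[tuple[int, str, str], list[str]]:
    groups: dict[tuple[int, str, str], list[str]] = defaultdict(list)
    for r in records:
        groups[(r.pos, r.cell_barcode, r.umi)].append(r.haplotype)
    return groups


def collapse_umis(records: Iterable[PhasedReadRecord]) -> CollapseResult:
    """Collapse reads to one observation per (pos, barcode, UMI) group.

    A group whose reads unanimously support one haplotype becomes a single
    :class:`UmiObservation` with ``read_support`` equal to the group size;
    a group containing both haplotypes is discarded and counted.
    """
    observations: list[UmiObservation] = []
    conflicts = 0
    for (pos, cb, umi), haps in _group_reads(records).items():
        uniq = set(haps)
        if len(uniq) == 1:
            observations.append(
                UmiObservation(pos, cb, umi, haps[0], len(haps))
            )
        else:
            conflicts += 1
    return CollapseResult(observations, conflicts)


def summarize_positions(
    records: Iterable[PhasedReadRecord],
) -> list[PositionSummary]:
    """Aggregate reads into one :class:`PositionSummary` per distinct position.

    Barcoding frequency counts every input read at the position, including
    reads inside haplotype-conflicted UMI groups; X1/X2 count only the
    unanimous UMI groups. Output is sorted by position.
    """
    records = list(records)
    freq: dict[int, int] = defaultdict(int)
    barcodes: dict[int, set[str]] = defaultdict(set)
    for r in records:
        freq[r.pos] += 1
        barcodes[r.pos].add(r.cell_barcode)

    per_pos_barcode: dict[int, dict[str, list[int]]] = defaultdict(dict)
    for (pos, cb, umi), haps in _group_reads(records).items():
        cell = per_pos_barcode[pos].setdefault(cb, [0, 0])
        uniq = set(haps)
        if len(uniq) == 1:
            cell[0 if haps[0] == "H1" else 1] += 1

    summaries: list[PositionSummary] = []
    for pos in sorted(freq):
        cells = per_pos_barcode.get(pos, {})
        # barcodes seen only through conflicted groups still count as observed
        for cb in barcodes[pos]:
            cells.setdefault(cb, [0, 0])
        per_barcode = {cb: (c[0], c[1]) for cb, c in sorted(cells.items())}
        x1 = sum(v[0] for v in per_barcode.values())
        x2 = sum(v[1] for v in per_barcode.values())
        s = PositionSummary(
            pos=pos,
            x1=x1,
            x2=x2,
            barcoding_frequency=freq[pos],
            n_barcodes=len(per_barcode),
            per_barcode=per_barcode,
        )
        s.validate()
        summaries.append(s)
    return summaries


def passes_skewing_filter(s: PositionSummary, t: FilterThresholds) -> bool:
    """The Fig-1-style funnel predicate, every bound inclusive."""
    return (
        t.freq_min <= s.barcoding_frequency <= t.freq_max
        and t.barcode_min <= s.n_barcodes <= t.barcode_max
        and s.x1 >= t.allele_min
        and s.x2 >= t.allele_min
    )


def filter_for_skewing(
    summaries: Sequence[PositionSummary],
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[PositionSummary]:
    """Retain positions passing the skewing funnel, preserving input order."""
    return [s for s in summaries if passes_skewing_filter(s, thresholds)]


def funnel_report(
    records: Sequence[PhasedReadRecord],
    summaries: Sequence[PositionSummary],
    filtered: Sequence[PositionSummary],
) -> FunnelReport:
    """Exact tallies for the funnel: total reads, distinct barcodes, positions."""
    return FunnelReport(
        total_reads=len(records),
        n_barcodes=len({r.cell_barcode for r in records}),
        candidate_positions=len(summaries),
        retained_positions=len(filtered),
    )


def summaries_to_frame(summaries: Sequence[PositionSummary]) -> pd.DataFrame:
    """Tabulate summaries as a DataFrame (pos, x1, x2, barcoding_frequency, n_barcodes)."""
    return pd.DataFrame(
        {
            "pos": [s.pos for s in summaries],
            "x1": [s.x1 for s in summaries],
            "x2": [s.x2 for s in summaries],
            "barcoding_frequency": [s.barcoding_frequency for s in summaries],
            "n_barcodes": [s.n_barcodes for s in summaries],
        }
    )
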