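"""Single-cell biallelic XCI-escape calling and gene annotation.

A position is called an escape candidate when it is observed in exactly one
cell (a single barcode) and that cell expresses *both* phased alleles with
at least ``allele_min`` UMI-collapsed counts each, with the position's read
coverage inside the usual [freq_min, freq_max] window. Because only one
barcode underlies the call, the per-cell counts coincide with the position
totals. Calls are annotated with overlapping genes from a BED interval set
and optionally cross-referenced against a known-escape gene list.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .aggregate import FilterThresholds, PositionSummary
from .phased_io import GeneAnnotation

__all__ = [
    "EscapeCall",
    "GeneMapResult",
    "call_escape",
    "map_to_genes",
    "cross_reference",
    "escape_calls_to_frame",
]


@dataclass(frozen=True, slots=True)
class EscapeCall:
    """A single-cell biallelic position: one barcode expressing both alleles."""

    pos: int
    cell_barcode: str
    x1: int
    x2: int
    barcoding_frequency: int
    genes: tuple[str, ...] = ()
    known_escape: bool | None = None


class GeneMapResult(NamedTuple):
    calls: list[EscapeCall]
    n_unmapped: int


def call_escape(
    summaries: Sequence[PositionSummary],
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[EscapeCall]:
    """Call escape candidates: one barcode, both alleles supported, depth in range.

    All bounds are inclusive: x1 >= allele_min, x2 >= allele_min and
    freq_min <= barcoding_frequency <= freq_max.
    """
    calls: list[EscapeCall] = []
    for s in summaries:
        if (
            s.n_barcodes == 1
            and s.x1 >= thresholds.allele_min
            and s.x2 >= thresholds.allele_min
            and thresholds.freq_min <= s.barcoding_frequency <= thresholds.freq_max
        ):
            barcode = next(iter(s.per_barcode))
            calls.append(
                EscapeCall(
                    pos=s.pos,
                    cell_barcode=barcode,
                    x1=s.x1,
                    x2=s.x2,
                    barcoding_frequency=s.barcoding_frequency,
                )
            )
    return calls


def map_to_genes(
    calls: Sequence[EscapeCall],
    annotations: Sequence[GeneAnnotation],
) -> GeneMapResult:
    """Annotate each call with all genes whose [start, end) contains it.

    Positions are 1-based; a call at ``pos`` overlaps a BED interval when
    ``start <= pos - 1 < end``. Calls with no overlap keep an empty gene
    list and are counted in the result.
    """
    tree = IntervalTree()
    for g in annotations:
        tree.addi(g.start, g.end, g.gene)
    annotated: list[EscapeCall] = []
    n_unmapped = 0
    for c in calls:
        genes = tuple(sorted(iv.data for iv in tree.at(c.pos - 1)))
        if not genes:
            n_unmapped += 1
        annotated.append(replace(c, genes=genes))
    return GeneMapResult(annotated, n_unmapped)


def cross_reference(
    genes: set[str] | Sequence[str], known: set[str]
) -> pd.DataFrame:
    """Flag each gene by membership in a known-escape list.

    Returns a DataFrame with columns ``gene`` (sorted) and ``known_escape``.
    """
    uniq = sorted(set(genes))
    return pd.DataFrame(
        {"gene": uniq, "known_escape": [g in known for g in uniq]}
    )


def escape_calls_to_frame(calls: Sequence[EscapeCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pos": [c.pos for c in calls],
            "cell_barcode": [c.cell_barcode for c in calls],
            "x1": [c.x1 for c in calls],
            "x2": [c.x2 for c in calls],
            "barcoding_frequency": [c.barcoding_frequency for c in calls],
            "genes": [";".join(c.genes) for c in calls],
            "known_escape": [c.known_escape for c in calls],
        }
    )
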