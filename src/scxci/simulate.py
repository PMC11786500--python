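"""Synthetic phased-read generator with known ground truth.

The generator emulates the data the pipeline consumes: per-read
observations of phased heterozygous chrX sites in barcoded, UMI-tagged
cells. Each heterozygous position is expressed by a random subset of the
cell pool; each expressing cell picks an active haplotype (H1 with
probability ``mosaic_fraction``), emits a shifted-Poisson number of UMIs of
that haplotype (flipping each with probability ``leak_rate`` to model
phasing noise and index hopping), and each UMI is sequenced as a
shifted-Poisson number of identical reads — giving the read > molecule >
cell count hierarchy of droplet scRNA-seq. Planted escape positions are
expressed in exactly one cell with at least three UMIs of *each*
haplotype, matching the operational single-cell biallelic criterion the
pipeline tests. Homozygous decoy positions emit a single haplotype label
everywhere and must never survive the heterozygous filters.

All counts use a shifted Poisson (1 + Poisson(mean - 1)), whose mean is
exactly the configured value with support >= 1. The same seed always
produces byte-identical output.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .phased_io import (
    PhasedReadRecord,
    write_phased_table,
)

__all__ = ["SimulationConfig", "simulate", "write_fixture", "TRUTH_COLUMNS"]

TRUTH_COLUMNS = ("pos", "true_type", "true_skew", "escape_barcode")

_ALPHABET = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated sample.

    ``mosaic_fraction`` is the probability a cell inactivates the H2
    haplotype, i.e. the expected skew toward H1; ``cells_per_position`` is
    the mean number of cells in which a position is observed (the barcode
    count layer); ``umis_per_cell_position`` and ``reads_per_umi`` set the
    molecule and coverage layers.
    """

    n_positions: int = 200
    n_cells: int = 200
    cells_per_position: float = 8.0
    mosaic_fraction: float = 0.7
    escape_rate: float = 0.02
    leak_rate: float = 0.01
    umis_per_cell_position: float = 3.0
    reads_per_umi: float = 1.8
    n_homozygous_decoys: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mosaic_fraction", "escape_rate", "leak_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_positions < 0 or self.n_homozygous_decoys < 0:
            raise ValueError("position counts must be non-negative")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for name in ("cells_per_position", "umis_per_cell_position", "reads_per_umi"):
            if getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be >= 1")


def _shifted_poisson(rng: np.random.Generator, mean: float) -> int:
    return 1 + int(rng.poisson(mean - 1.0))


def _random_tag(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_ALPHABET, size=length))


def _unique_tags(rng: np.random.Generator, n: int, length: int) -> list[str]:
    tags: list[str] = []
    seen: set[str] = set()
    while len(tags) < n:
        t = _random_tag(rng, length)
        if t not in seen:
            seen.add(t)
            tags.append(t)
    return tags


class _Emitter:
    """Accumulates read records with fresh read ids and per-cell-unique UMIs."""

    def __init__(self, rng: np.random.Generator) -> None:
        self.rng = rng
        self.records: list[PhasedReadRecord] = []
        self._read_counter = 0

    def emit_umi(
        self, pos: int, bases: dict[str, str], barcode: str,
        used_umis: set[str], haplotype: str, n_reads: int,
    ) -> None:
        while True:
            umi = _random_tag(self.rng, 10)
            if umi not in used_umis:
                used_umis.add(umi)
                break
        for _ in range(n_reads):
            self._read_counter += 1
            self.records.append(
                PhasedReadRecord(
                    chrom="chrX",
                    pos=pos,
                    base=bases[haplotype],
                    haplotype=haplotype,
                    cell_barcode=barcode,
                    umi=umi,
                    read_id=f"r{self._read_counter:08d}",
                )
            )


def simulate(
    config: SimulationConfig,
) -> tuple[list[PhasedReadRecord], pd.DataFrame]:
    """Generate phased-read records and their ground-truth table.

    Returns the records (grouped by position, ascending) and a truth
    DataFrame with one row per position: ``pos``, ``true_type`` (skewed |
    random | escape | homozygous), ``true_skew`` (the expected major-allele
    fraction) and ``escape_barcode`` (empty unless planted escape).
    """
    rng = np.random.default_rng(config.seed)
    pi = config.mosaic_fraction

    n_total = config.n_positions + config.n_homozygous_decoys
    if n_total == 0:
        return [], pd.DataFrame(columns=list(TRUTH_COLUMNS))

    # distinct chrX-scale coordinates
    positions: list[int] = []
    seen: set[int] = set()
    while len(positions) < n_total:
        p = int(rng.integers(1, 155_000_000))
        if p not in seen:
            seen.add(p)
            positions.append(p)
    positions.sort()

    het_positions = positions[: config.n_positions]
    decoy_positions = positions[config.n_positions:]
    n_escape = int(round(config.escape_rate * config.n_positions))
    escape_set = set(
        rng.choice(config.n_positions, size=n_escape, replace=False).tolist()
    ) if n_escape else set()

    barcodes = _unique_tags(rng, config.n_cells, 16)
    emitter = _Emitter(rng)
    het_type = "random" if abs(pi - 0.5) < 1e-12 else "skewed"
    het_skew = max(pi, 1.0 - pi)
    truth_rows: list[tuple[int, str, float, str]] = []

    for idx, pos in enumerate(het_positions):
        ref, alt = rng.choice(4, size=2, replace=False)
        bases = {"H1": str(_ALPHABET[ref]), "H2": str(_ALPHABET[alt])}
        if idx in escape_set:
            barcode = barcodes[int(rng.integers(config.n_cells))]
            used: set[str] = set()
            for hap in ("H1", "H2"):
                n_umis = max(3, _shifted_poisson(rng, config.umis_per_cell_position))
                for _ in range(n_umis):
                    emitter.emit_umi(
                        pos, bases, barcode, used, hap,
                        _shifted_poisson(rng, config.reads_per_umi),
                    )
            truth_rows.append((pos, "escape", 0.5, barcode))
            continue

        k = min(
            _shifted_poisson(rng, config.cells_per_position), config.n_cells
        )
        cell_idx = rng.choice(config.n_cells, size=k, replace=False)
        for ci in cell_idx:
            barcode = barcodes[int(ci)]
            active = "H1" if rng.random() < pi else "H2"
            used = set()
            n_umis = _shifted_poisson(rng, config.umis_per_cell_position)
            for _ in range(n_umis):
                hap = active
                if config.leak_rate > 0 and rng.random() < config.leak_rate:
                    hap = "H2" if active == "H1" else "H1"
                emitter.emit_umi(
                    pos, bases, barcode, used, hap,
                    _shifted_poisson(rng, config.reads_per_umi),
                )
        truth_rows.append((pos, het_type, het_skew, ""))

    for pos in decoy_positions:
        base = str(_ALPHABET[int(rng.integers(4))])
        hap = "H1" if rng.random() < 0.5 else "H2"
        bases = {hap: base}
        k = min(
            _shifted_poisson(rng, config.cells_per_position), config.n_cells
        )
        cell_idx = rng.choice(config.n_cells, size=k, replace=False)
        for ci in cell_idx:
            used = set()
            n_umis = _shifted_poisson(rng, config.umis_per_cell_position)
            for _ in range(n_umis):
                emitter.emit_umi(
                    pos, bases, barcodes[int(ci)], used, hap,
                    _shifted_poisson(rng, config.reads_per_umi),
                )
        truth_rows.append((pos, "homozygous", 1.0, ""))

    truth = pd.DataFrame(truth_rows, columns=list(TRUTH_COLUMNS))
    truth = truth.sort_values("pos", kind="mergesort").reset_index(drop=True)
    emitter.records.sort(key=lambda r: r.pos)
    return emitter.records, truth


def write_fixture(
    config: SimulationConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Simulate one sample and write a complete on-disk fixture.

    Writes the phased table, a BED4 of synthetic genes tiling the simulated
    positions, a known-escape gene list (covering planted escape genes and
    one non-escape gene, so cross-referencing sees both flags), the truth
    table and the configuration. Returns the paths keyed by role.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, truth = simulate(config)

    paths = {
        "phased_table": out_dir / "phased_table.tsv",
        "genes_bed": out_dir / "genes.bed",
        "known_escape": out_dir / "known_escape_genes.txt",
        "truth": out_dir / "truth.tsv",
        "config": out_dir / "config.yaml",
    }
    write_phased_table(records, paths["phased_table"])

    positions = sorted(truth["pos"].tolist())
    escape_pos = set(truth.loc[truth["true_type"] == "escape", "pos"])
    gene_rows: list[tuple[str, int, int, str]] = []
    escape_genes: list[str] = []
    other_genes: list[str] = []
    for gi in range(0, len(positions), 4):
        chunk = positions[gi : gi + 4]
        name = f"SYNG{gi // 4 + 1:04d}"
        start = max(0, chunk[0] - 1 - 50)
        end = chunk[-1] - 1 + 50
        gene_rows.append(("chrX", start, end, name))
        if any(p in escape_pos for p in chunk):
            escape_genes.append(name)
        else:
            other_genes.append(name)
    with paths["genes_bed"].open("w", encoding="utf-8") as fh:
        for chrom, start, end, name in gene_rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")

    known = list(escape_genes)
    if other_genes:
        known.append(other_genes[0])
    with paths["known_escape"].open("w", encoding="utf-8") as fh:
        for g in known:
            fh.write(g + "\n")

    truth.to_csv(paths["truth"], sep="\t", index=False)
    with paths["config"].open("w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
    return paths
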