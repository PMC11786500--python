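from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from scxci.aggregate import PositionSummary
from scxci.phased_io import PhasedReadRecord
from scxci.simulate import SimulationConfig, simulate

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_summary(
    pos: int, x1: int, x2: int, freq: int | None = None, n_barcodes: int = 1
) -> PositionSummary:
    """Build a consistent PositionSummary, packing all UMIs into one barcode."""
    if freq is None:
        freq = x1 + x2
    per_barcode = {f"BC{pos}_{i:03d}": (0, 0) for i in range(1, n_barcodes)}
    per_barcode[f"BC{pos}_000"] = (x1, x2)
    s = PositionSummary(
        pos=pos,
        x1=x1,
        x2=x2,
        barcoding_frequency=freq,
        n_barcodes=n_barcodes,
        per_barcode=per_barcode,
    )
    s.validate()
    return s


def random_records(
    rng: np.random.Generator,
    n: int,
    n_positions: int = 10,
    n_cells: int = 5,
    n_umis: int = 8,
) -> list[PhasedReadRecord]:
    """Unstructured random reads for grouping/tally oracles."""
    return [
        PhasedReadRecord(
            chrom="chrX",
            pos=int(rng.integers(1, n_positions + 1)) * 1000,
            base="ACGT"[int(rng.integers(4))],
            haplotype="H1" if rng.random() < 0.5 else "H2",
            cell_barcode=f"CELL{int(rng.integers(n_cells)):02d}",
            umi=f"UMI{int(rng.integers(n_umis)):02d}",
            read_id=f"r{i}",
        )
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def small_sim():
    """A modest simulated sample shared across tests (seeded, deterministic)."""
    config = SimulationConfig(
        n_positions=80,
        n_cells=120,
        cells_per_position=8.0,
        mosaic_fraction=0.7,
        escape_rate=0.05,
        leak_rate=0.01,
        umis_per_cell_position=3.0,
        reads_per_umi=1.8,
        n_homozygous_decoys=15,
        seed=42,
    )
    records, truth = simulate(config)
    return config, records, truth
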