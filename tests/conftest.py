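import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from poolanchor.core_io import BACRecord, PhysicalMap
from poolanchor.pooling import PoolLayout, SignalMatrix

GEOMETRY = (20, 16, 24)


def tiny_records() -> list[BACRecord]:
    """Twelve BACs: three contigs with overlaps, a contig pair for the
    semi-automated case, a lone candidate well for the manual case, a
    disjoint-placement pair, and an unplaced singleton."""
    return [
        # ctg1: chain of three, consecutive overlaps only
        BACRecord("B01", 1, "A", 1, "ctg1", 0, 150_000),
        BACRecord("B02", 2, "B", 2, "ctg1", 100_000, 250_000),
        BACRecord("B03", 3, "C", 3, "ctg1", 200_000, 350_000),
        # ctg2: overlapping pair
        BACRecord("B04", 4, "D", 4, "ctg2", 500_000, 650_000),
        BACRecord("B05", 5, "E", 5, "ctg2", 600_000, 750_000),
        # ctg3: single placed BAC
        BACRecord("B06", 6, "F", 6, "ctg3", 900_000, 1_000_000),
        # unplaced singleton
        BACRecord("B07", 7, "G", 7, None, None, None),
        # ctg4: manual-completion target at (P03, F, 11)
        BACRecord("B08", 3, "F", 11, "ctg4", 1_200_000, 1_350_000),
        # ctg5: semi-automated pair at (P10, H, 5) / (P11, I, 5)
        BACRecord("B10", 10, "H", 5, "ctg5", 2_000_000, 2_150_000),
        BACRecord("B11", 11, "I", 5, "ctg5", 2_100_000, 2_250_000),
        # ctg6/ctg7: disjoint contigs for duplicated placements
        BACRecord("B12", 12, "J", 6, "ctg6", 3_000_000, 3_150_000),
        BACRecord("B13", 13, "K", 7, "ctg7", 4_000_000, 4_150_000),
    ]


@pytest.fixture
def tiny_map() -> PhysicalMap:
    bin_of = {"ctg1": "bin1", "ctg2": "bin1", "ctg4": "bin2", "ctg5": "bin2",
              "ctg6": "bin2", "ctg7": "bin2"}
    return PhysicalMap(tiny_records(), bin_of=bin_of)


@pytest.fixture
def tiny_layout(tiny_map) -> PoolLayout:
    return PoolLayout.from_physical_map(tiny_map, *GEOMETRY)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)


def normalised_matrix(layout: PoolLayout, rows: dict[str, dict[str, float]],
                      baseline: float = 1.0) -> SignalMatrix:
    """Build a probe_normalised matrix with given per-pool values (baseline
    elsewhere) — convenient for hand-constructed scoring cases."""
    pool_ids = layout.pool_ids()
    data = pd.DataFrame(baseline, index=list(rows), columns=pool_ids, dtype=float)
    for probe, overrides in rows.items():
        for pool_id, value in overrides.items():
            data.loc[probe, pool_id] = value
    return SignalMatrix(data=data, state="probe_normalised")
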