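import numpy as np
import pandas as pd
import pytest

from homolog_check import CellMap, Dataset, NucleusParams, OrganismMode


@pytest.fixture
def small_params() -> NucleusParams:
    """Three mid-sized autosomes, moderate coverage: fast but non-trivial."""
    return NucleusParams(
        n_autosomes=3,
        chromosome_lengths=(100_000_000, 80_000_000, 60_000_000),
        reads_per_chromosome=60.0,
        seed=11,
    )


def make_cell(rows, cell_id="c1", mode=OrganismMode.INTERPHASE) -> CellMap:
    """Cell from (chrom, haplotype, pos_bp, x, y, z) tuples."""
    df = pd.DataFrame(
        rows, columns=["chrom", "haplotype", "pos_bp", "x_um", "y_um", "z_um"]
    )
    return CellMap(cell_id, df, organism_mode=mode)


def make_dataset(*cells) -> Dataset:
    return Dataset.from_cells(cells, provenance="test")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
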