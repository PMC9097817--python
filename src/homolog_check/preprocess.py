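"""Preprocessing of allele-resolved read tables.

Stages, in pipeline order: artificial pronuclear fusion (zygotes), common-
scale rescaling of the two haplotype clouds, fixed-width genomic binning with
per-bin coordinate averaging, shared-bin homolog alignment, and read-count
filters.  All operations return new objects; inputs are never mutated.
"""

from __future__ import annotations

import enum
import operator
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .igs_io import CellMap, Dataset, OrganismMode

__all__ = [
    "BinnedCell",
    "BinnedHomologPair",
    "FilterScope",
    "fuse_pronuclei",
    "rescale_pronuclei",
    "bin_cell",
    "shared_homolog_bins",
    "filter_by_reads",
]

_COORDS = ["x_um", "y_um", "z_um"]


@dataclass
class BinnedCell:
    """Per-(chromosome, haplotype, bin) mean coordinates of one cell.

    ``entries`` has columns chrom, haplotype, bin, n_reads, x_um, y_um, z_um;
    bin = floor(pos_bp / resolution) with half-open 0-based bins.
    """

    cell_id: str
    resolution: int
    entries: pd.DataFrame

    def bins(self, chromosome: str, haplotype: str) -> pd.DataFrame:
        df = self.entries
        return df[(df["chrom"] == str(chromosome)) & (df["haplotype"] == haplotype)]

    def chromosomes(self) -> list[str]:
        return sorted(self.entries["chrom"].unique())


@dataclass
class BinnedHomologPair:
    """Row-aligned maternal/paternal coordinates over shared genomic bins."""

    chromosome: str
    bin_indices: np.ndarray  # strictly increasing
    G_M: np.ndarray  # (n, 3)
    G_P: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.bin_indices = np.asarray(self.bin_indices, dtype=np.int64)
        self.G_M = np.asarray(self.G_M, dtype=float).reshape(-1, 3)
        self.G_P = np.asarray(self.G_P, dtype=float).reshape(-1, 3)
        n = len(self.bin_indices)
        if self.G_M.shape[0] != n or self.G_P.shape[0] != n:
            raise ValueError("G_M/G_P rows must match bin_indices")
        if n > 1 and not np.all(np.diff(self.bin_indices) > 0):
            raise ValueError("bin_indices must be strictly increasing")

    @property
    def n(self) -> int:
        return len(self.bin_indices)


class FilterScope(str, enum.Enum):
    CELL_TOTAL = "cell_total"
    CHROMOSOME_HAPLOTYPE = "chromosome_haplotype"


# ---------------------------------------------------------------------------
# Pronuclear fusion and rescaling (zygotes)
# ---------------------------------------------------------------------------


def _haplotype_coords(cell: CellMap, hap: str) -> np.ndarray:
    return cell.coords(haplotype=hap)


def fuse_pronuclei(cell: CellMap, force: bool = False) -> CellMap:
    """Translate the paternal read cloud onto the maternal centroid.

    Emulates fusion of the two pronuclei of a zygote by translating the
    whole paternal cloud so its centroid coincides with the maternal
    centroid.  Maternal reads are unchanged; the operation is idempotent.

    Raises on interphase cells unless ``force``, and on an empty haplotype
    cloud (naming the cell).
    """
    if cell.organism_mode is not OrganismMode.ZYGOTE and not force:
        raise ValueError(
            f"cell {cell.cell_id!r}: fuse_pronuclei expects a zygote "
            "(pass force=True to override)"
        )
    cm = _haplotype_coords(cell, "M")
    cp = _haplotype_coords(cell, "P")
    if len(cm) == 0 or len(cp) == 0:
        raise ValueError(f"cell {cell.cell_id!r}: a haplotype cloud is empty, cannot fuse")
    shift = cm.mean(axis=0) - cp.mean(axis=0)
    reads = cell.reads.copy()
    mask = reads["haplotype"] == "P"
    reads.loc[mask, _COORDS] = reads.loc[mask, _COORDS].to_numpy() + shift
    return cell.with_reads(reads)


def rescale_pronuclei(cell: CellMap, force: bool = False) -> CellMap:
    """Scale both haplotype clouds to a common RMS radius.

    Each phased cloud is scaled about the common centroid (mean of all phased
    reads) so that both root-mean-square radii equal the geometric mean of
    the two original RMS radii — a symmetric choice of the "common scale".
    Idempotent.  Interphase cells pass through unchanged unless ``force``.
    """
    if cell.organism_mode is not OrganismMode.ZYGOTE and not force:
        return cell
    cm = _haplotype_coords(cell, "M")
    cp = _haplotype_coords(cell, "P")
    if len(cm) < 2 or len(cp) < 2:
        raise ValueError(
            f"cell {cell.cell_id!r}: need >= 2 reads per haplotype to rescale"
        )
    center = np.vstack([cm, cp]).mean(axis=0)
    rms = {}
    for hap, coords in (("M", cm), ("P", cp)):
        r = float(np.sqrt(np.mean(np.sum((coords - center) ** 2, axis=1))))
        if r == 0.0:
            raise ValueError(f"cell {cell.cell_id!r}: degenerate {hap} cloud (RMS radius 0)")
        rms[hap] = r
    target = float(np.sqrt(rms["M"] * rms["P"]))
    reads = cell.reads.copy()
    for hap in ("M", "P"):
        mask = reads["haplotype"] == hap
        coords = reads.loc[mask, _COORDS].to_numpy()
        reads.loc[mask, _COORDS] = center + (target / rms[hap]) * (coords - center)
    return cell.with_reads(reads)


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------


def bin_cell(cell: CellMap, resolution: int = 1_000_000) -> BinnedCell:
    """Average phased read coordinates into fixed-width genomic bins.

    Bins are half-open ``[k*resolution, (k+1)*resolution)``, 0-based; the
    per-bin representative is the unweighted mean of member read coordinates.
    Unphased reads are excluded.
    """
    if resolution < 1:
        raise ValueError("resolution must be >= 1")
    phased = cell.phased
    if len(phased) == 0:
        entries = pd.DataFrame(
            columns=["chrom", "haplotype", "bin", "n_reads", *_COORDS]
        )
        return BinnedCell(cell.cell_id, resolution, entries)
    df = phased.assign(bin=phased["pos_bp"] // resolution)
    grouped = (
        df.groupby(["chrom", "haplotype", "bin"], sort=True)
        .agg(n_reads=("pos_bp", "size"), **{c: (c, "mean") for c in _COORDS})
        .reset_index()
    )
    grouped["bin"] = grouped["bin"].astype(np.int64)
    return BinnedCell(cell.cell_id, int(resolution), grouped)


def shared_homolog_bins(binned: BinnedCell, chromosome: str) -> BinnedHomologPair:
    """Row-aligned maternal/paternal bin coordinates for one chromosome.

    ``bin_indices`` is the sorted intersection of the maternal and paternal
    bin sets; the result may be empty (downstream operations enforce their
    own minimum n).
    """
    chromosome = str(chromosome)
    bm = binned.bins(chromosome, "M").set_index("bin")
    bp = binned.bins(chromosome, "P").set_index("bin")
    shared = np.array(sorted(set(bm.index) & set(bp.index)), dtype=np.int64)
    g_m = bm.loc[shared, _COORDS].to_numpy() if len(shared) else np.empty((0, 3))
    g_p = bp.loc[shared, _COORDS].to_numpy() if len(shared) else np.empty((0, 3))
    return BinnedHomologPair(chromosome, shared, g_m, g_p)


# ---------------------------------------------------------------------------
# Read-count filters
# ---------------------------------------------------------------------------

_COMPARATORS = {
    ">": operator.gt,
    ">=": operator.ge,
    "<": operator.lt,
    "<=": operator.le,
    "gt": operator.gt,
    "ge": operator.ge,
    "lt": operator.lt,
    "le": operator.le,
}


def filter_by_reads(
    dataset: Dataset,
    scope: FilterScope | str,
    threshold: int,
    comparator: str = ">=",
) -> tuple[list, pd.DataFrame]:
    """Select analysis units by phased read count; data are never modified.

    For ``CELL_TOTAL`` the unit is a cell and the count its total phased
    reads; for ``CHROMOSOME_HAPLOTYPE`` the unit is (cell, chromosome) and
    the count is the *minimum* of the two haplotype read counts, so that a
    rule like "exclude chromosomes with <3 reads" (``threshold=3,
    comparator=">="``) drops a chromosome whenever either homolog is too
    sparse for paired analyses.

    Returns ``(kept_units, report)``: kept unit keys (cell ids, or (cell id,
    chromosome) tuples) and a per-unit report with count and kept flag.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    cmp = _COMPARATORS.get(comparator)
    if cmp is None:
        raise ValueError(f"unknown comparator {comparator!r}")
    scope = FilterScope(scope)
    rows, kept = [], []
    if scope is FilterScope.CELL_TOTAL:
        for cell in dataset:
            n = cell.n_reads()
            ok = bool(cmp(n, threshold))
            rows.append((cell.cell_id, n, ok))
            if ok:
                kept.append(cell.cell_id)
        report = pd.DataFrame(rows, columns=["cell_id", "n_reads", "kept"])
    else:
        for cell in dataset:
            counts = cell.phased.groupby(["chrom", "haplotype"]).size()
            for chrom in sorted(set(cell.phased["chrom"]), key=str):
                n_m = int(counts.get((chrom, "M"), 0))
                n_p = int(counts.get((chrom, "P"), 0))
                ok = bool(cmp(min(n_m, n_p), threshold))
                rows.append((cell.cell_id, chrom, n_m, n_p, ok))
                if ok:
                    kept.append((cell.cell_id, chrom))
        report = pd.DataFrame(
            rows, columns=["cell_id", "chrom", "n_reads_M", "n_reads_P", "kept"]
        )
    return kept, report
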