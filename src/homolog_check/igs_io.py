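"""Data model and delimited-table I/O for allele-resolved 3D genome imaging reads.

In situ genome sequencing (IGS) yields, per single cell, a table of sequenced
reads each carrying a genomic coordinate, a haplotype assignment (maternal,
paternal, or unphased) and a 3D spatial coordinate.  This module defines the
in-memory containers used throughout the package — :class:`LocusRead`,
:class:`CellMap`, :class:`Dataset` — and readers/writers for the plain
delimited-text format the pipeline consumes and the simulator emits.

Unphased reads are carried by I/O (round-trips losslessly) but are excluded
from every analysis operation downstream.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Haplotype",
    "OrganismMode",
    "LocusRead",
    "CellMap",
    "Dataset",
    "CANONICAL_COLUMNS",
    "read_igs_table",
    "write_igs_table",
    "summarize_reads",
]


class Haplotype(str, enum.Enum):
    """Allelic origin of a read."""

    MATERNAL = "M"
    PATERNAL = "P"
    UNPHASED = "U"


class OrganismMode(str, enum.Enum):
    """Nuclear context of a cell.

    ZYGOTE cells have two spatially separate pronuclei (all-maternal and
    all-paternal clouds) and are the only cells eligible for artificial
    pronuclear fusion and rescaling.  INTERPHASE cells have a single nucleus.
    """

    ZYGOTE = "zygote"
    INTERPHASE = "interphase"


#: Canonical column names of the on-disk table.  A *dialect* mapping lets
#: differently-headed tables (e.g. the deposited IGS supplementary tables) be
#: adapted without editing the data.
CANONICAL_COLUMNS = ("cell_id", "chrom", "haplotype", "pos_bp", "x_um", "y_um", "z_um")

_REQUIRED = set(CANONICAL_COLUMNS)

#: Accepted spellings of haplotype codes (case-insensitive).
_HAPLOTYPE_CODES: Mapping[str, str] = {
    "m": "M",
    "mat": "M",
    "maternal": "M",
    "p": "P",
    "pat": "P",
    "paternal": "P",
    "u": "U",
    "unphased": "U",
    "none": "U",
    "na": "U",
    "nan": "U",
}

_SEX_CHROMOSOMES = {"X", "Y", "M", "MT", "CHRX", "CHRY", "CHRM", "CHRMT"}


@dataclass(frozen=True)
class LocusRead:
    """One allele-resolved imaged read.

    Parameters
    ----------
    cell_id
        Identifier of the cell the read belongs to.
    chromosome
        Chromosome label (opaque string, e.g. ``"1"``..``"19"``).
    haplotype
        Maternal / paternal / unphased assignment.
    genomic_pos
        Genomic coordinate in base pairs (non-negative).
    coord
        3-vector of spatial coordinates in micrometres.
    """

    cell_id: str
    chromosome: str
    haplotype: Haplotype
    genomic_pos: int
    coord: np.ndarray

    def __post_init__(self) -> None:
        if self.genomic_pos < 0:
            raise ValueError(f"genomic_pos must be >= 0, got {self.genomic_pos}")
        coord = np.asarray(self.coord, dtype=float)
        if coord.shape != (3,):
            raise ValueError(f"coord must be a 3-vector, got shape {coord.shape}")
        if not np.all(np.isfinite(coord)):
            raise ValueError("coord components must be finite")
        object.__setattr__(self, "coord", coord)


def _chromosome_sort_key(label: str):
    try:
        return (0, int(label), "")
    except ValueError:
        return (1, 0, label)


def _infer_autosomes(labels: Iterable[str]) -> list[str]:
    """Autosome labels present, sorted; sex/mitochondrial chromosomes excluded."""
    auto = {lab for lab in labels if lab.upper() not in _SEX_CHROMOSOMES}
    return sorted(auto, key=_chromosome_sort_key)


class CellMap:
    """All reads of one cell, with per-(chromosome, haplotype) selectors.

    Reads are stored as a :class:`pandas.DataFrame` with the canonical columns
    (minus ``cell_id``); :meth:`iter_reads` exposes them as
    :class:`LocusRead` objects.
    """

    def __init__(
        self,
        cell_id: str,
        reads: pd.DataFrame,
        organism_mode: OrganismMode = OrganismMode.INTERPHASE,
        autosome_set: list[str] | None = None,
    ) -> None:
        self.cell_id = str(cell_id)
        self.organism_mode = OrganismMode(organism_mode)
        df = reads.reset_index(drop=True).copy()
        missing = {"chrom", "haplotype", "pos_bp", "x_um", "y_um", "z_um"} - set(df.columns)
        if missing:
            raise ValueError(f"CellMap reads missing columns: {sorted(missing)}")
        df["chrom"] = df["chrom"].astype(str)
        df["haplotype"] = df["haplotype"].astype(str)
        df["pos_bp"] = df["pos_bp"].astype(np.int64)
        for c in ("x_um", "y_um", "z_um"):
            df[c] = df[c].astype(float)
        if (df["pos_bp"] < 0).any():
            raise ValueError(f"cell {cell_id}: negative genomic positions")
        if not np.all(np.isfinite(df[["x_um", "y_um", "z_um"]].to_numpy())):
            raise ValueError(f"cell {cell_id}: non-finite coordinates")
        bad = set(df["haplotype"]) - {"M", "P", "U"}
        if bad:
            raise ValueError(f"cell {cell_id}: unknown haplotype codes {sorted(bad)}")
        self.reads = df
        if autosome_set is None:
            autosome_set = _infer_autosomes(df["chrom"].unique())
        self.autosome_set = list(autosome_set)

    # -- selectors ---------------------------------------------------------

    @property
    def phased(self) -> pd.DataFrame:
        """Reads with a maternal or paternal assignment."""
        return self.reads[self.reads["haplotype"] != "U"]

    def select(
        self, chromosome: str | None = None, haplotype: Haplotype | str | None = None
    ) -> pd.DataFrame:
        """Phased reads, optionally restricted to one chromosome / haplotype."""
        df = self.phased
        if chromosome is not None:
            df = df[df["chrom"] == str(chromosome)]
        if haplotype is not None:
            df = df[df["haplotype"] == Haplotype(haplotype).value]
        return df

    def coords(self, chromosome: str | None = None, haplotype=None) -> np.ndarray:
        """(n, 3) array of spatial coordinates of the selected phased reads."""
        return self.select(chromosome, haplotype)[["x_um", "y_um", "z_um"]].to_numpy()

    def n_reads(self, phased_only: bool = True) -> int:
        return len(self.phased) if phased_only else len(self.reads)

    def iter_reads(self) -> Iterator[LocusRead]:
        for row in self.reads.itertuples(index=False):
            yield LocusRead(
                self.cell_id,
                row.chrom,
                Haplotype(row.haplotype),
                int(row.pos_bp),
                np.array([row.x_um, row.y_um, row.z_um]),
            )

    def with_reads(self, reads: pd.DataFrame) -> "CellMap":
        """Copy of this cell with a replacement read table (metadata kept)."""
        return CellMap(self.cell_id, reads, self.organism_mode, list(self.autosome_set))

    def __len__(self) -> int:
        return len(self.reads)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"CellMap({self.cell_id!r}, {len(self.reads)} reads "
            f"({len(self.phased)} phased), {self.organism_mode.value})"
        )


@dataclass
class Dataset:
    """A collection of cells with unique ids."""

    cells: dict[str, CellMap] = field(default_factory=dict)
    provenance: str = ""

    @classmethod
    def from_cells(cls, cells: Iterable[CellMap], provenance: str = "") -> "Dataset":
        out: dict[str, CellMap] = {}
        for cell in cells:
            if cell.cell_id in out:
                raise ValueError(f"duplicate cell_id {cell.cell_id!r}")
            out[cell.cell_id] = cell
        return cls(out, provenance)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.cells)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def __iter__(self) -> Iterator[CellMap]:
        return iter(self.cells.values())

    def __getitem__(self, cell_id: str) -> CellMap:
        return self.cells[cell_id]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table of all reads with cell_id and organism columns."""
        frames = []
        for cell in self:
            df = cell.reads.copy()
            df.insert(0, "cell_id", cell.cell_id)
            df["organism_mode"] = cell.organism_mode.value
            frames.append(df)
        if not frames:
            return pd.DataFrame(columns=[*CANONICAL_COLUMNS, "organism_mode"])
        return pd.concat(frames, ignore_index=True)[[*CANONICAL_COLUMNS, "organism_mode"]]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_igs_table(
    path,
    dialect: Mapping[str, str] | None = None,
    organism_mode: OrganismMode | str = OrganismMode.INTERPHASE,
    on_unknown_haplotype: str = "error",
) -> Dataset:
    """Read a delimited read table (TSV/CSV sniffed by extension) into a Dataset.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    dialect
        Optional mapping from canonical column names (``cell_id``, ``chrom``,
        ``haplotype``, ``pos_bp``, ``x_um``, ``y_um``, ``z_um``) to the actual
        headers in the file, so deposited tables can be loaded unedited.
    organism_mode
        Mode assigned to every cell unless the file carries an
        ``organism_mode`` column.
    on_unknown_haplotype
        ``"error"`` (default) raises on an unrecognized haplotype code;
        ``"skip"`` drops the offending rows with a warning.

    Raises
    ------
    ValueError
        On missing required columns, non-numeric coordinate fields (named by
        row and column), or unknown haplotype codes when not skipping.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    if dialect:
        rename = {src: canon for canon, src in dialect.items() if src in raw.columns}
        raw = raw.rename(columns=rename)
    missing = _REQUIRED - set(raw.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")

    # numeric validation with row-level diagnostics; the actual conversion
    # uses astype(float), which parses exactly (to_numeric may round)
    for col in ("pos_bp", "x_um", "y_um", "z_um"):
        bad = pd.to_numeric(raw[col], errors="coerce").isna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, plus header line
            raise ValueError(
                f"{path}: non-numeric value {raw[col][bad.idxmax()]!r} "
                f"in column {col!r} at line {row}"
            )
        raw[col] = raw[col].astype(float)
    if (raw["pos_bp"] % 1 != 0).any() or (raw["pos_bp"] < 0).any():
        raise ValueError(f"{path}: pos_bp must be non-negative integers")
    raw["pos_bp"] = raw["pos_bp"].astype(np.int64)

    codes = raw["haplotype"].str.strip().str.lower()
    mapped = codes.map(_HAPLOTYPE_CODES)
    unknown = mapped.isna()
    if unknown.any():
        labels = sorted(set(raw["haplotype"][unknown]))
        if on_unknown_haplotype == "skip":
            warnings.warn(
                f"{path}: skipping {int(unknown.sum())} rows with unknown "
                f"haplotype codes {labels}",
                stacklevel=2,
            )
            raw, mapped = raw[~unknown], mapped[~unknown]
        else:
            raise ValueError(f"{path}: unknown haplotype codes {labels}")
    raw = raw.assign(haplotype=mapped)

    default_mode = OrganismMode(organism_mode)
    cells = []
    for cell_id, group in raw.groupby("cell_id", sort=False):
        mode = default_mode
        if "organism_mode" in group.columns:
            modes = set(group["organism_mode"])
            if len(modes) > 1:
                raise ValueError(f"{path}: cell {cell_id!r} has mixed organism_mode")
            mode = OrganismMode(next(iter(modes)))
        cells.append(
            CellMap(
                str(cell_id),
                group[["chrom", "haplotype", "pos_bp", "x_um", "y_um", "z_um"]],
                organism_mode=mode,
            )
        )
    return Dataset.from_cells(cells, provenance=str(path))


def write_igs_table(dataset: Dataset, path) -> None:
    """Write a Dataset to delimited text (TSV/CSV by extension).

    Floats are written with 17 significant digits (lossless for float64),
    so ``read(write(D))`` reproduces every read exactly (up to row order).
    """
    path = Path(path)
    df = dataset.to_frame()
    df.to_csv(path, sep=_sep_for(path), index=False, float_format="%.17g")


def summarize_reads(dataset: Dataset) -> dict:
    """Phased read-count summary.

    Returns a dict with ``per_cell`` (cell_id, n_phased_reads),
    ``per_cell_chrom_hap`` (cell_id, chrom, haplotype, n_reads) and
    ``median_reads_per_cell`` (median of the per-cell phased counts).
    Counts are of phased reads only; cells whose reads are all unphased
    count 0.  Raises on an empty dataset.
    """
    if dataset.n_cells == 0:
        raise ValueError("summarize_reads: empty dataset")
    per_cell = pd.DataFrame(
        {
            "cell_id": dataset.cell_ids,
            "n_phased_reads": [c.n_reads() for c in dataset],
        }
    )
    rows = []
    for cell in dataset:
        grp = cell.phased.groupby(["chrom", "haplotype"], sort=True).size()
        for (chrom, hap), n in grp.items():
            rows.append((cell.cell_id, chrom, hap, int(n)))
    per_unit = pd.DataFrame(rows, columns=["cell_id", "chrom", "haplotype", "n_reads"])
    return {
        "per_cell": per_cell,
        "per_cell_chrom_hap": per_unit,
        "median_reads_per_cell": float(per_cell["n_phased_reads"].median()),
    }
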