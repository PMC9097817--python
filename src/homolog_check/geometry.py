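"""Geometric primitives: centroids, distance matrices, multi-way distances.

Includes the eight-fold higher-order distance set of a homologous locus
triplet: given one homologous locus (maternal/paternal coordinate pair) on
each of three distinct chromosomes, there are 2^3 = 8 allele assignments;
each yields a three-way distance (sum of the distances of the three chosen
points to their centroid).  The minimum's share of the total,
``min_proportion``, is the dominance statistic: under uniformity (all eight
equal) it is exactly 1/8 = 0.125.

All distances are unsquared Euclidean, and every operation is invariant
under a simultaneous rigid motion of all coordinates.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .igs_io import CellMap
from .preprocess import BinnedCell

__all__ = [
    "DistanceMatrix",
    "TripletDistanceSet",
    "centroid",
    "chromosome_centroids",
    "pairwise_distance_matrix",
    "three_way_distance",
    "eight_way_distances",
    "homologous_triplets",
]

_ALLELE_CHOICES = tuple(itertools.product("MP", repeat=3))


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative Euclidean distance matrix with labelled rows."""

    labels: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("values must be n x n with n = len(labels)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("distance matrix has non-finite entries")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric within 1e-12")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be exactly 0")
        if np.any(self.values < 0):
            raise ValueError("distances must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass
class TripletDistanceSet:
    """The eight candidate three-way distances of one homologous triplet."""

    chromosomes: tuple[str, str, str]
    bins: tuple[int, int, int]
    eight_distances: dict = field(default_factory=dict)  # (a1,a2,a3) -> float

    def __post_init__(self) -> None:
        if len(set(self.chromosomes)) != 3:
            raise ValueError("triplet chromosomes must be distinct")
        if set(self.eight_distances) != set(_ALLELE_CHOICES):
            raise ValueError("eight_distances must cover all 2^3 allele choices")

    @property
    def total(self) -> float:
        # fsum: correctly rounded, so eight equal distances give a total of
        # exactly 8x and a min_proportion of exactly 0.125
        return math.fsum(self.eight_distances.values())

    @property
    def minimum(self) -> float:
        return float(min(self.eight_distances.values()))

    @property
    def min_proportion(self) -> float:
        """min(eight) / sum(eight), in (0, 0.125]."""
        total = self.total
        if total == 0.0:
            raise ValueError("fully degenerate triplet: all eight distances are zero")
        return self.minimum / total


# ---------------------------------------------------------------------------


def centroid(points) -> np.ndarray:
    """Componentwise arithmetic mean (center of mass) of >= 1 points."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) == 0:
        raise ValueError("centroid of empty point set is undefined")
    return pts.mean(axis=0)


def chromosome_centroids(cell: CellMap, autosomes_only: bool = True) -> dict:
    """Centroid of every chromosome homolog's phased reads.

    Returns a map (chromosome, haplotype) -> 3-vector; homologs with zero
    reads are absent.  Invariant to read order.
    """
    phased = cell.phased
    if autosomes_only:
        phased = phased[phased["chrom"].isin(cell.autosome_set)]
    out = {}
    for (chrom, hap), grp in phased.groupby(["chrom", "haplotype"], sort=True):
        out[(chrom, hap)] = grp[["x_um", "y_um", "z_um"]].to_numpy().mean(axis=0)
    return out


def pairwise_distance_matrix(G: np.ndarray, labels=None) -> DistanceMatrix:
    """Euclidean distance matrix between the rows of an (n, 3) array."""
    G = np.asarray(G, dtype=float).reshape(-1, 3)
    if len(G) == 0:
        raise ValueError("need at least one point")
    if not np.all(np.isfinite(G)):
        raise ValueError("non-finite coordinates")
    if labels is None:
        labels = np.arange(len(G))
    values = squareform(pdist(G)) if len(G) > 1 else np.zeros((1, 1))
    return DistanceMatrix(np.asarray(labels), values)


def three_way_distance(p1, p2, p3) -> float:
    """Sum of the distances of three points to their common centroid."""
    pts = np.asarray([p1, p2, p3], dtype=float)
    c = pts.mean(axis=0)
    return float(np.linalg.norm(pts - c, axis=1).sum())


def eight_way_distances(
    pairs,
    chromosomes: tuple[str, str, str] = ("c1", "c2", "c3"),
    bins: tuple[int, int, int] = (0, 0, 0),
) -> TripletDistanceSet:
    """All 2^3 three-way distances of three homologous (M, P) coordinate pairs.

    ``pairs`` is a sequence of three ``(maternal_coord, paternal_coord)``
    pairs, one per chromosome.  For each allele choice (a1, a2, a3) in
    {M, P}^3 the three chosen points' three-way distance is computed.
    Raises if all eight distances are zero (min_proportion undefined).
    """
    if len(pairs) != 3:
        raise ValueError("need exactly three (maternal, paternal) pairs")
    lookup = [
        {"M": np.asarray(m, dtype=float), "P": np.asarray(p, dtype=float)}
        for m, p in pairs
    ]
    if not all(np.all(np.isfinite(d[h])) for d in lookup for h in "MP"):
        raise ValueError("non-finite coordinates in triplet")
    eight = {
        choice: three_way_distance(
            lookup[0][choice[0]], lookup[1][choice[1]], lookup[2][choice[2]]
        )
        for choice in _ALLELE_CHOICES
    }
    result = TripletDistanceSet(tuple(chromosomes), tuple(bins), eight)
    result.min_proportion  # raise now on fully degenerate input
    return result


def homologous_triplets(
    binned: BinnedCell,
    chromosome_subset,
    max_triplets: int | None = None,
    seed: int | None = None,
) -> list[TripletDistanceSet]:
    """Enumerate homologous locus triplets across three distinct chromosomes.

    A homologous locus is a (chromosome, bin) whose bin holds reads on both
    haplotypes (matched at bin granularity after per-bin averaging).
    Triplets take one homologous locus from each of three distinct
    chromosomes of the subset; the count is
    ``sum_{c1<c2<c3} n_c1 * n_c2 * n_c3`` with n_c homologous bins on c.
    With fewer than three eligible chromosomes the list is empty.

    ``max_triplets`` caps the output by seeded uniform subsampling (dense
    synthetic data can otherwise explode combinatorially).
    """
    subset = sorted({str(c) for c in chromosome_subset}, key=str)
    if len(subset) < 3:
        raise ValueError("need at least 3 chromosomes in the subset")
    loci: dict[str, list[tuple[int, np.ndarray, np.ndarray]]] = {}
    for chrom in subset:
        bm = binned.bins(chrom, "M").set_index("bin")
        bp = binned.bins(chrom, "P").set_index("bin")
        shared = sorted(set(bm.index) & set(bp.index))
        if shared:
            cols = ["x_um", "y_um", "z_um"]
            loci[chrom] = [
                (int(b), bm.loc[b, cols].to_numpy(), bp.loc[b, cols].to_numpy())
                for b in shared
            ]
    eligible = [c for c in subset if c in loci]
    results: list[TripletDistanceSet] = []
    combos = []
    for c1, c2, c3 in itertools.combinations(eligible, 3):
        for l1 in loci[c1]:
            for l2 in loci[c2]:
                for l3 in loci[c3]:
                    combos.append(((c1, c2, c3), (l1, l2, l3)))
    if max_triplets is not None and len(combos) > max_triplets:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(combos), size=max_triplets, replace=False)
        combos = [combos[i] for i in sorted(idx)]
    for (c1, c2, c3), (l1, l2, l3) in combos:
        results.append(
            eight_way_distances(
                [(l1[1], l1[2]), (l2[1], l2[2]), (l3[1], l3[2])],
                chromosomes=(c1, c2, c3),
                bins=(l1[0], l2[0], l3[0]),
            )
        )
    return results
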