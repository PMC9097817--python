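"""Synthetic diploid-nucleus generator with known ground truth.

Emulates the statistical structure of allele-resolved 3D genome imaging data:
per-cell sparse reads along chromosomes, two haplotypes per autosome,
chromosome-territory clustering, tunable maternal/paternal configuration
divergence, optional unfused pronuclei (all-maternal vs all-paternal clouds,
offset and differently scaled), and Gaussian localization noise.

Each chromosome backbone is a smoothed 3D random walk confined to a spherical
territory by a restoring force toward the territory center (leaky integration
of the walk increments, an Ornstein-Uhlenbeck-style confinement).  The
confinement sets a genomic correlation length ``backbone_correlation_mb``
beyond which positions along the fiber decorrelate — without it a free walk
carries territory-scale serial correlation at every genomic distance, which
permutation tests on locus-labelled configurations are highly sensitive to.
The paternal backbone is a convex blend of (a) a rigid-motion copy of the
maternal backbone and (b) an independently drawn backbone, with blend weight
``homolog_divergence`` (rho): rho = 0 makes the paternal configuration an
exact rigid-motion image of the maternal one (a Procrustes-equivalence
oracle), rho = 1 makes the two homolog configurations independent.

No polymer-physics realism (no excluded volume, no loop extrusion) is
attempted: the generator targets the geometric/statistical structure the
downstream assumption tests rely on, nothing more.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .igs_io import CellMap, Dataset, OrganismMode

__all__ = [
    "TerritoryMode",
    "NucleusParams",
    "GroundTruth",
    "mouse_like_params",
    "human_like_params",
    "simulate_backbone",
    "simulate_cell",
    "simulate_zygote",
    "simulate_cohort",
]


class TerritoryMode(str, enum.Enum):
    """How the 2K territory centers are arranged inside the nucleus."""

    RANDOM = "random"
    ADJACENT_HOMOLOGS = "adjacent_homologs"
    SEPARATED_HOMOLOGS = "separated_homologs"


#: Mouse autosome (chr1-19) lengths rounded to 10 Mb.
MOUSE_AUTOSOME_LENGTHS_BP: tuple[int, ...] = tuple(
    int(mb * 1_000_000)
    for mb in (200, 180, 160, 160, 150, 150, 150, 130, 120, 130,
               120, 120, 120, 120, 100, 100, 90, 90, 60)
)

#: Human autosome (chr1-22) lengths rounded to 10 Mb.
HUMAN_AUTOSOME_LENGTHS_BP: tuple[int, ...] = tuple(
    int(mb * 1_000_000)
    for mb in (250, 240, 200, 190, 180, 170, 160, 150, 140, 130, 140,
               130, 110, 110, 100, 90, 80, 80, 60, 60, 50, 50)
)


@dataclass(frozen=True)
class NucleusParams:
    """Parameters of one simulated nucleus.

    Attributes
    ----------
    n_autosomes
        Number of autosomes K (two homologs each).
    chromosome_lengths
        Length of each autosome in bp (len == K).
    nucleus_radius
        Radius of the nuclear (or pronuclear) sphere, micrometres.
    territory_radius
        Radius of one chromosome territory, micrometres.
    homolog_divergence
        rho in [0, 1]; blend weight of the independent backbone in the
        paternal homolog (0 = rigid-motion copy, 1 = independent).
    territory_mode
        Arrangement of territory centers (interphase cells).
    pronuclear_offset
        Distance d (micrometres) between maternal and paternal pronuclear
        centers (zygote mode only).
    pronuclear_scale_ratio
        Factor s by which the paternal cloud is scaled about its own
        centroid (zygote mode only).
    reads_per_chromosome
        Expected read count lambda per homolog; actual counts are Poisson.
    localization_noise
        Isotropic Gaussian sigma (micrometres) added to each read coordinate.
    backbone_step
        Step length of the backbone random walk, micrometres.
    backbone_correlation_mb
        Genomic distance (Mb) over which positions along the confined fiber
        decorrelate; territory confinement is what limits the correlation.
    shared_read_positions
        When True, both homologs of a chromosome are sampled at the same
        genomic positions (useful for exact-equivalence oracles); default
        False, matching an assay that does not preferentially target common
        loci on companion homologs.
    seed
        Non-negative base seed; per-cell and per-chromosome substreams are
        derived from it so adding cells never perturbs earlier cells.
    """

    n_autosomes: int = 19
    chromosome_lengths: tuple[int, ...] = MOUSE_AUTOSOME_LENGTHS_BP
    nucleus_radius: float = 5.0
    territory_radius: float = 1.5
    homolog_divergence: float = 1.0
    territory_mode: TerritoryMode = TerritoryMode.RANDOM
    pronuclear_offset: float = 0.0
    pronuclear_scale_ratio: float = 1.0
    reads_per_chromosome: float = 100.0
    localization_noise: float = 0.1
    backbone_step: float = 0.3
    backbone_correlation_mb: float = 1.0
    smoothing_window: int = 5
    shared_read_positions: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_autosomes < 1:
            raise ValueError("n_autosomes must be >= 1")
        if len(self.chromosome_lengths) != self.n_autosomes:
            raise ValueError("chromosome_lengths must have length n_autosomes")
        if any(l <= 0 for l in self.chromosome_lengths):
            raise ValueError("chromosome lengths must be positive")
        if not 0.0 <= self.homolog_divergence <= 1.0:
            raise ValueError("homolog_divergence must be in [0, 1]")
        if self.nucleus_radius <= 0 or self.territory_radius <= 0:
            raise ValueError("radii must be positive")
        if self.territory_radius > self.nucleus_radius:
            raise ValueError("infeasible geometry: territory_radius > nucleus_radius")
        if self.reads_per_chromosome <= 0 or self.pronuclear_scale_ratio <= 0:
            raise ValueError("reads_per_chromosome and pronuclear_scale_ratio must be > 0")
        if self.localization_noise < 0 or self.pronuclear_offset < 0:
            raise ValueError("localization_noise and pronuclear_offset must be >= 0")
        if self.backbone_step < 0:
            raise ValueError("backbone_step must be >= 0")
        if self.backbone_correlation_mb <= 0:
            raise ValueError("backbone_correlation_mb must be > 0")
        if self.smoothing_window < 1:
            raise ValueError("smoothing_window must be >= 1")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")

    @property
    def chromosome_labels(self) -> list[str]:
        return [str(i + 1) for i in range(self.n_autosomes)]


def mouse_like_params(**overrides) -> NucleusParams:
    """Mouse-like preset: K = 19 autosomes, lengths ~ mouse autosomes."""
    return replace(NucleusParams(), **overrides)


def human_like_params(**overrides) -> NucleusParams:
    """Human-like preset: K = 22 autosomes, lengths ~ human autosomes."""
    base = NucleusParams(
        n_autosomes=22,
        chromosome_lengths=HUMAN_AUTOSOME_LENGTHS_BP,
        reads_per_chromosome=6.0,
    )
    return replace(base, **overrides)


@dataclass
class GroundTruth:
    """Per-homolog backbone polylines and the placement actually applied."""

    backbones: dict = field(default_factory=dict)  # (chrom, hap) -> (n, 3) vertices
    genomic_grids: dict = field(default_factory=dict)  # (chrom, hap) -> (n,) bp grid
    territory_centers: dict = field(default_factory=dict)  # (chrom, hap) -> 3-vector
    pronuclear_offset_applied: float = 0.0
    pronuclear_scales: dict = field(default_factory=dict)  # hap -> scale factor


# ---------------------------------------------------------------------------
# Primitive generators
# ---------------------------------------------------------------------------


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_backbone(
    n_vertices: int,
    step: float,
    smoothing_window: int = 5,
    seed=None,
) -> np.ndarray:
    """Smoothed 3D random walk: a stand-in for a contiguous chromatin fiber.

    Unit-direction steps of length ``step`` are accumulated and then smoothed
    by a centered moving average of width ``smoothing_window`` (window 1 is
    the raw walk; wider windows reduce curvature).  ``step = 0`` yields a
    degenerate constant polyline.  Deterministic given the seed.
    """
    if n_vertices < 2:
        raise ValueError("n_vertices must be >= 2")
    if step < 0:
        raise ValueError("step must be >= 0")
    if smoothing_window < 1:
        raise ValueError("smoothing_window must be >= 1")
    rng = _as_rng(seed)
    directions = rng.normal(size=(n_vertices - 1, 3))
    norms = np.linalg.norm(directions, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    walk = np.vstack([np.zeros(3), np.cumsum(step * directions / norms, axis=0)])
    if smoothing_window == 1:
        return walk
    w = min(smoothing_window, n_vertices)
    kernel = np.ones(w) / w
    # pad with edge values so endpoints are averaged over in-range vertices
    pad = w // 2
    padded = np.pad(walk, ((pad, w - 1 - pad), (0, 0)), mode="edge")
    smoothed = np.column_stack(
        [np.convolve(padded[:, k], kernel, mode="valid") for k in range(3)]
    )
    return smoothed


def _uniform_in_ball(rng: np.random.Generator, radius: float, size: int) -> np.ndarray:
    """Uniform points in a ball of given radius."""
    directions = rng.normal(size=(size, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    radii = radius * rng.random(size) ** (1.0 / 3.0)
    return directions * radii[:, None]


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random proper rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _rng_for(params: NucleusParams, cell_index: int, role: int, sub: int = 0):
    """Substream keyed by (seed, cell, role, sub): stable under cohort growth."""
    return np.random.default_rng(
        np.random.SeedSequence([int(params.seed), int(cell_index), int(role), int(sub)])
    )


def _place_territories(
    params: NucleusParams, rng: np.random.Generator, center: np.ndarray | None = None
) -> dict:
    """Territory centers for one interphase nucleus, per territory_mode."""
    params.validate()
    margin = max(params.nucleus_radius - params.territory_radius, 0.1 * params.nucleus_radius)
    if center is None:
        center = np.zeros(3)
    labels = params.chromosome_labels
    centers: dict = {}
    mode = TerritoryMode(params.territory_mode)
    if mode is TerritoryMode.RANDOM:
        pts = _uniform_in_ball(rng, margin, 2 * params.n_autosomes) + center
        for i, lab in enumerate(labels):
            centers[(lab, "M")] = pts[2 * i]
            centers[(lab, "P")] = pts[2 * i + 1]
    elif mode is TerritoryMode.ADJACENT_HOMOLOGS:
        offset = min(0.3 * params.territory_radius, 0.2 * margin)
        maternal = _rejection_spread(rng, margin, params.n_autosomes, 2.5 * offset)
        for i, lab in enumerate(labels):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            centers[(lab, "M")] = maternal[i] + center
            centers[(lab, "P")] = maternal[i] + offset * direction + center
    elif mode is TerritoryMode.SEPARATED_HOMOLOGS:
        r = 0.8 * margin
        for lab in labels:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            centers[(lab, "M")] = center + r * direction
            centers[(lab, "P")] = center - r * direction
    else:  # pragma: no cover
        raise ValueError(f"unknown territory mode {mode}")
    return centers


def _rejection_spread(
    rng: np.random.Generator, radius: float, n: int, min_sep: float, max_tries: int = 2000
) -> np.ndarray:
    """n points in a ball with pairwise separation >= min_sep (best effort)."""
    points: list[np.ndarray] = []
    tries = 0
    while len(points) < n and tries < max_tries:
        cand = _uniform_in_ball(rng, radius, 1)[0]
        tries += 1
        if all(np.linalg.norm(cand - p) >= min_sep for p in points):
            points.append(cand)
    while len(points) < n:  # fall back: accept regardless of separation
        points.append(_uniform_in_ball(rng, radius, 1)[0])
    return np.asarray(points)


#: Backbone vertex spacing along the genome, bp.
_VERTEX_SPACING_BP = 500_000
#: RMS radius of a confined backbone relative to its territory radius.
_TERRITORY_FILL = 0.6


def _n_vertices_for(length_bp: int) -> int:
    """Backbone resolution: one vertex per 0.5 Mb, at least 8."""
    return max(8, int(round(length_bp / _VERTEX_SPACING_BP)))


def _confined_backbone(
    params: NucleusParams, n_vertices: int, length_bp: int, rng: np.random.Generator
) -> np.ndarray:
    """Territory-confined fiber: leaky integration of smoothed-walk increments.

    A free smoothed random walk is turned into a stationary confined fiber by
    ``x[i+1] = phi * x[i] + increment[i]`` with ``phi = exp(-dg / L)`` (dg =
    vertex spacing, L = ``backbone_correlation_mb``), then centered and
    scaled to an RMS radius of ``_TERRITORY_FILL * territory_radius``.
    """
    walk = simulate_backbone(
        n_vertices, params.backbone_step, params.smoothing_window, rng
    )
    increments = np.diff(walk, axis=0, prepend=np.zeros((1, 3)))
    spacing_mb = (length_bp / max(n_vertices - 1, 1)) / 1e6
    phi = float(np.exp(-spacing_mb / params.backbone_correlation_mb))
    confined = lfilter([1.0], [1.0, -phi], increments, axis=0)
    confined = confined - confined.mean(axis=0)
    rms = float(np.sqrt(np.mean(np.sum(confined**2, axis=1))))
    if rms > 0:
        confined *= _TERRITORY_FILL * params.territory_radius / rms
    return confined


def _chromosome_backbones(
    params: NucleusParams, cell_index: int, chrom_index: int, centers_M, centers_P
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Maternal/paternal backbone vertices plus the shared genomic grid."""
    length = params.chromosome_lengths[chrom_index]
    n_vert = _n_vertices_for(length)
    grid = np.linspace(0.0, float(length), n_vert)
    rng = _rng_for(params, cell_index, 1, chrom_index)
    maternal = _confined_backbone(params, n_vert, length, rng)
    rotation = _random_rotation(rng)
    rigid = maternal @ rotation.T
    independent = _confined_backbone(params, n_vert, length, rng)
    rho = params.homolog_divergence
    paternal = (1.0 - rho) * rigid + rho * independent
    return maternal + centers_M, paternal + centers_P, grid


def _sample_reads(
    params: NucleusParams,
    cell_index: int,
    chrom_index: int,
    backbone_M: np.ndarray,
    backbone_P: np.ndarray,
    grid: np.ndarray,
) -> pd.DataFrame:
    """Poisson(lambda) reads per homolog at uniform genomic positions."""
    rng = _rng_for(params, cell_index, 2, chrom_index)
    length = params.chromosome_lengths[chrom_index]
    n_m = rng.poisson(params.reads_per_chromosome)
    n_p = rng.poisson(params.reads_per_chromosome)
    pos_m = rng.integers(0, length, size=n_m)
    if params.shared_read_positions:
        n_p, pos_p = n_m, pos_m.copy()
    else:
        pos_p = rng.integers(0, length, size=n_p)
    rows = []
    for hap, pos, backbone in (("M", pos_m, backbone_M), ("P", pos_p, backbone_P)):
        coords = np.column_stack(
            [np.interp(pos, grid, backbone[:, k]) for k in range(3)]
        )
        if params.localization_noise > 0:
            coords = coords + rng.normal(
                scale=params.localization_noise, size=coords.shape
            )
        label = params.chromosome_labels[chrom_index]
        for p, c in zip(pos, coords):
            rows.append((label, hap, int(p), c[0], c[1], c[2]))
    return pd.DataFrame(
        rows, columns=["chrom", "haplotype", "pos_bp", "x_um", "y_um", "z_um"]
    )


# ---------------------------------------------------------------------------
# Cell- and cohort-level generators
# ---------------------------------------------------------------------------


def _build_cell(
    params: NucleusParams,
    cell_id: str,
    cell_index: int,
    centers: dict,
    organism_mode: OrganismMode,
) -> tuple[CellMap, GroundTruth]:
    truth = GroundTruth(territory_centers=dict(centers))
    frames = []
    for ci, lab in enumerate(params.chromosome_labels):
        backbone_M, backbone_P, grid = _chromosome_backbones(
            params, cell_index, ci, centers[(lab, "M")], centers[(lab, "P")]
        )
        truth.backbones[(lab, "M")] = backbone_M
        truth.backbones[(lab, "P")] = backbone_P
        truth.genomic_grids[(lab, "M")] = grid
        truth.genomic_grids[(lab, "P")] = grid.copy()
        frames.append(
            _sample_reads(params, cell_index, ci, backbone_M, backbone_P, grid)
        )
    reads = pd.concat(frames, ignore_index=True)
    cell = CellMap(
        cell_id,
        reads,
        organism_mode=organism_mode,
        autosome_set=params.chromosome_labels,
    )
    return cell, truth


def simulate_cell(
    params: NucleusParams, cell_id: str = "cell_000", cell_index: int = 0
) -> tuple[CellMap, GroundTruth]:
    """Simulate one interphase nucleus.

    2K territory centers are placed per ``territory_mode`` inside the nuclear
    sphere; reads are sampled per homolog as Poisson(lambda) uniform genomic
    positions interpolated along the homolog backbone, plus isotropic
    Gaussian localization noise.
    """
    params.validate()
    rng_t = _rng_for(params, cell_index, 0)
    centers = _place_territories(params, rng_t)
    return _build_cell(params, cell_id, cell_index, centers, OrganismMode.INTERPHASE)


def simulate_zygote(
    params: NucleusParams, cell_id: str = "zygote_000", cell_index: int = 0
) -> tuple[CellMap, GroundTruth]:
    """Simulate one zygote with unfused pronuclei.

    All maternal territories occupy a sphere centered at ``-d/2`` along x and
    all paternal territories a sphere at ``+d/2`` (d = ``pronuclear_offset``);
    the paternal cloud is then scaled by ``pronuclear_scale_ratio`` about its
    own centroid.
    """
    params.validate()
    rng_t = _rng_for(params, cell_index, 0)
    d = params.pronuclear_offset
    center_M = np.array([-d / 2.0, 0.0, 0.0])
    center_P = np.array([+d / 2.0, 0.0, 0.0])
    random_params = replace(params, territory_mode=TerritoryMode.RANDOM)
    centers_Mside = _place_territories(random_params, rng_t, center=center_M)
    centers_Pside = _place_territories(random_params, rng_t, center=center_P)
    centers = {}
    for lab in params.chromosome_labels:
        centers[(lab, "M")] = centers_Mside[(lab, "M")]
        centers[(lab, "P")] = centers_Pside[(lab, "P")]
    cell, truth = _build_cell(params, cell_id, cell_index, centers, OrganismMode.ZYGOTE)

    s = params.pronuclear_scale_ratio
    truth.pronuclear_offset_applied = d
    truth.pronuclear_scales = {"M": 1.0, "P": s}
    if s != 1.0:
        reads = cell.reads.copy()
        mask = reads["haplotype"] == "P"
        coords = reads.loc[mask, ["x_um", "y_um", "z_um"]].to_numpy()
        centroid = coords.mean(axis=0)
        reads.loc[mask, ["x_um", "y_um", "z_um"]] = centroid + s * (coords - centroid)
        cell = cell.with_reads(reads)
        for lab in params.chromosome_labels:
            bb = truth.backbones[(lab, "P")]
            truth.backbones[(lab, "P")] = centroid + s * (bb - centroid)
    return cell, truth


def simulate_cohort(
    params: NucleusParams | Sequence[NucleusParams],
    n_cells: int | None = None,
    mode: OrganismMode | str = OrganismMode.INTERPHASE,
    return_truths: bool = False,
):
    """Simulate a cohort of independent cells as a Dataset.

    Either pass one ``NucleusParams`` plus ``n_cells`` (cells differ only via
    per-cell derived seed substreams), or a sequence of per-cell params.
    Deterministic: the same master seed yields an identical Dataset, and cell
    i's reads do not depend on how many cells follow it.
    """
    if isinstance(params, NucleusParams):
        if n_cells is None or n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        params_list = [params] * n_cells
    else:
        params_list = list(params)
        if not params_list:
            raise ValueError("params_list must be non-empty")
    mode = OrganismMode(mode)
    sim = simulate_zygote if mode is OrganismMode.ZYGOTE else simulate_cell
    prefix = "zygote" if mode is OrganismMode.ZYGOTE else "cell"
    cells, truths = [], {}
    for i, p in enumerate(params_list):
        cell_id = f"{prefix}_{i:03d}"
        cell, truth = sim(p, cell_id=cell_id, cell_index=i)
        cells.append(cell)
        truths[cell_id] = truth
    dataset = Dataset.from_cells(cells, provenance="synthetic")
    if return_truths:
        return dataset, truths
    return dataset
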