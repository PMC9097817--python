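"""Assumption-evaluation programs over a dataset of allele-resolved cells.

Four programs, each probing an assumption invoked by a family of diploid
3D-reconstruction methods, run on imaged (or simulated) 3D read tables:

* **DCP** ("different chromosome partners") — is the nearest chromosome to a
  homolog, measured between chromosome centroids, its homolog partner?
  Aggregated per-homolog flags are tested against the random-positioning
  null p0 = 1/(2K - 1) with an exact binomial test.
* **ECM** ("equal centers of mass") — do homolog-pair centroid distances
  resemble non-homologous centroid distances?  Per-cell two-sample t-tests.
* **Dom8** — among the eight candidate three-way distances of a homologous
  locus triplet, is the minimum dominant (min/total < 0.125/4)?
* **Salvage** — are the maternal and paternal intra-chromosomal distance
  matrices of a homolog pair equal?  GRV association tests on binned
  distance matrices, confirmed by Procrustes permutation tests on the
  aligned configurations, plus intra- vs inter-homolog distance summaries.

Zygote cells are put through artificial pronuclear fusion and common-scale
rescaling first (configurable); interphase cells are used as-is.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .geometry import chromosome_centroids, homologous_triplets, pairwise_distance_matrix
from .igs_io import CellMap, Dataset, OrganismMode
from .preprocess import bin_cell, fuse_pronuclei, rescale_pronuclei, shared_homolog_bins
from .stats import binomial_exact, bonferroni, grv_test, protest_test, welch_t

__all__ = [
    "EvalConfig",
    "EvalReport",
    "eval_dcp",
    "eval_ecm",
    "eval_dom8",
    "eval_salvage_grv",
    "run_report",
    "SECTIONS",
]


@dataclass(frozen=True)
class EvalConfig:
    """Settings shared across evaluation sections.

    ``verdict_convention`` maps GRV/protest outcomes to a similar/different
    verdict.  The permutation null is *no association*, so rejection is
    evidence of similarity; ``"reject_means_associated"`` (default) calls a
    significant test "similar".  ``"reject_means_different"`` applies the
    opposite reading.  The convention in force is recorded in every report.
    """

    resolution: int = 1_000_000
    fuse: bool = True
    rescale: bool = True
    alpha: float = 0.05
    bonferroni_m: int | None = None  # None = automatic per section
    min_cell_reads: int = 500  # strict > for Dom8/salvage cell eligibility
    min_chrom_reads: int = 3  # exclusion <; per-haplotype, ECM eligibility
    dom8_threshold: float = 0.125 / 4
    dom8_chromosomes: tuple[str, ...] = ("1", "2", "3", "4", "5")
    dom8_max_triplets: int | None = 2000
    grv_method: str = "auto"
    grv_n_perm: int = 999
    protest_n_perm: int = 999
    min_loci: int = 4
    salvage_selection: str = "reads_gt"  # or "max_chrom"
    salvage_min_reads: int = 500  # strict >, total over both haplotypes
    ecm_alternative: str = "greater"  # homolog distances exceed non-homolog
    verdict_convention: str = "reject_means_associated"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.resolution < 1 or self.dom8_threshold <= 0:
            raise ValueError("resolution and dom8_threshold must be positive")
        if self.verdict_convention not in (
            "reject_means_associated",
            "reject_means_different",
        ):
            raise ValueError(f"unknown verdict_convention {self.verdict_convention!r}")
        if self.salvage_selection not in ("reads_gt", "max_chrom"):
            raise ValueError(f"unknown salvage_selection {self.salvage_selection!r}")


@dataclass
class EvalReport:
    """Per-section result tables plus aggregates and run metadata."""

    sections: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    version: str = ""
    errors: dict = field(default_factory=dict)

    def to_json(self, indent: int = 2) -> str:
        payload = {
            "version": self.version,
            "config": self.config,
            "sections": {
                name: {
                    "aggregate": sec["aggregate"],
                    "table": sec["table"].to_dict(orient="records"),
                }
                for name, sec in self.sections.items()
            },
            "errors": self.errors,
        }
        return json.dumps(payload, indent=indent, sort_keys=True, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# Shared helpers
# ---------------------------------------------------------------------------


def _preprocess_cell(cell: CellMap, config: EvalConfig) -> CellMap:
    """Fuse and rescale zygotes per config; interphase cells pass through."""
    if cell.organism_mode is OrganismMode.ZYGOTE:
        if config.fuse:
            cell = fuse_pronuclei(cell)
        if config.rescale:
            cell = rescale_pronuclei(cell)
    return cell


def _chrom_sort_key(item):
    chrom = item if isinstance(item, str) else item[0]
    try:
        return (0, int(chrom), "", item)
    except (ValueError, TypeError):
        return (1, 0, str(chrom), item)


def _sub_seed(config: EvalConfig, *keys: int) -> int:
    """Stable per-unit seed below 2**31 derived from the config seed."""
    ss = np.random.SeedSequence([int(config.seed), *map(int, keys)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


# ---------------------------------------------------------------------------
# DCP: nearest chromosome centroid is the homolog partner?
# ---------------------------------------------------------------------------


def eval_dcp(dataset: Dataset, config: EvalConfig) -> dict:
    """Nearest-centroid-is-homolog counting with an exact binomial test.

    For every homolog with a defined centroid whose partner also has one,
    the nearest of the other centroids (2K - 1 competitors when all are
    present) is found; the homolog is *flagged* when its partner is the
    unique nearest.  The aggregate flag count over all trials is tested
    against the random-positioning null p0 = 1/(2K - 1) (one-sided,
    greater), Bonferroni-adjusted over the K chromosomes.  A per-cell
    "possesses >= 1 flagged chromosome" indicator is reported alongside.
    """
    rows = []
    k_values = set()
    for cell in dataset:
        prepped = _preprocess_cell(cell, config)
        K = len(prepped.autosome_set)
        if K < 2:
            raise ValueError(f"cell {cell.cell_id!r}: DCP needs K >= 2 autosomes")
        k_values.add(K)
        cents = chromosome_centroids(prepped)
        keys = sorted(cents, key=_chrom_sort_key)
        coords = np.array([cents[k] for k in keys])
        for i, (chrom, hap) in enumerate(keys):
            partner = (chrom, "P" if hap == "M" else "M")
            if partner not in cents:
                continue  # partner has no centroid: not a valid trial
            dists = np.linalg.norm(coords - coords[i], axis=1)
            dists[i] = np.inf
            j_partner = keys.index(partner)
            d_partner = dists[j_partner]
            others = np.delete(dists, [i, j_partner])
            # unique-minimizer rule: ties do not count as homolog-nearest
            flagged = bool(len(others) == 0 or d_partner < others.min())
            rows.append(
                {
                    "cell_id": cell.cell_id,
                    "chrom": chrom,
                    "haplotype": hap,
                    "d_partner": float(d_partner),
                    "d_nearest_other": float(others.min()) if len(others) else np.nan,
                    "partner_nearest": flagged,
                    "n_competitors": int(np.isfinite(dists).sum()),
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        return {"table": table, "aggregate": {"note": "no valid DCP trials"}}
    K = max(k_values)
    p0 = 1.0 / (2 * K - 1)
    n_trials = len(table)
    n_flagged = int(table["partner_nearest"].sum())
    test = binomial_exact(n_flagged, n_trials, p0, alternative="greater")
    m = config.bonferroni_m if config.bonferroni_m is not None else K
    test.adjusted_p = bonferroni([test.p_value], m=m)[0]
    per_cell = table.groupby("cell_id")["partner_nearest"].any()
    aggregate = {
        "n_cells": int(dataset.n_cells),
        "n_cells_flagged": int(per_cell.sum()),
        "n_trials": n_trials,
        "n_flagged": n_flagged,
        "flag_fraction": n_flagged / n_trials,
        "p0": p0,
        "binomial_p": test.p_value,
        "binomial_p_bonferroni": test.adjusted_p,
        "bonferroni_m": m,
    }
    return {"table": table, "aggregate": aggregate}


# ---------------------------------------------------------------------------
# ECM: homolog vs non-homolog centroid distances
# ---------------------------------------------------------------------------


def eval_ecm(dataset: Dataset, config: EvalConfig) -> dict:
    """Per-cell t-tests of homolog vs non-homolog centroid distances.

    Chromosomes with a haplotype read count below ``min_chrom_reads`` are
    excluded.  Group A holds the homolog-pair centroid distances (one per
    eligible chromosome), group B every other pairwise distance between the
    eligible homolog centroids.  Welch's t-test (one-sided by default:
    homolog distances exceed non-homolog) per cell; fractions significant
    at alpha and at the Bonferroni-adjusted level are aggregated.
    """
    rows = []
    for cell in dataset:
        prepped = _preprocess_cell(cell, config)
        counts = prepped.phased.groupby(["chrom", "haplotype"]).size()
        eligible = [
            c
            for c in prepped.autosome_set
            if counts.get((c, "M"), 0) >= config.min_chrom_reads
            and counts.get((c, "P"), 0) >= config.min_chrom_reads
        ]
        cents = chromosome_centroids(prepped)
        keys = [(c, h) for c in eligible for h in "MP" if (c, h) in cents]
        homolog_d, other_d = [], []
        for a in range(len(keys)):
            for b in range(a + 1, len(keys)):
                d = float(np.linalg.norm(cents[keys[a]] - cents[keys[b]]))
                if keys[a][0] == keys[b][0]:
                    homolog_d.append(d)
                else:
                    other_d.append(d)
        row = {
            "cell_id": cell.cell_id,
            "n_eligible_chroms": len(eligible),
            "n_homolog_pairs": len(homolog_d),
            "n_other_pairs": len(other_d),
            "mean_homolog_dist": float(np.mean(homolog_d)) if homolog_d else np.nan,
            "mean_other_dist": float(np.mean(other_d)) if other_d else np.nan,
        }
        if len(homolog_d) < 2 or len(other_d) < 2:
            row.update(t_statistic=np.nan, p_value=np.nan,
                       skip_reason="insufficient centroid pairs")
        else:
            res = welch_t(homolog_d, other_d, alternative=config.ecm_alternative)
            row.update(t_statistic=res.statistic, p_value=res.p_value, skip_reason="")
        rows.append(row)
    table = pd.DataFrame(rows)
    tested = table[table["skip_reason"] == ""] if len(table) else table
    m = config.bonferroni_m if config.bonferroni_m is not None else max(len(tested), 1)
    if len(tested):
        adj = bonferroni(list(tested["p_value"]), m=m)
        table.loc[tested.index, "p_bonferroni"] = adj
        n_sig = int((tested["p_value"] < config.alpha).sum())
        n_sig_adj = int((np.asarray(adj) < config.alpha).sum())
    else:
        table["p_bonferroni"] = np.nan
        n_sig = n_sig_adj = 0
    aggregate = {
        "n_cells": int(dataset.n_cells),
        "n_tested": int(len(tested)),
        "n_skipped": int(len(table) - len(tested)),
        "n_significant": n_sig,
        "n_significant_bonferroni": n_sig_adj,
        "frac_significant": n_sig / len(tested) if len(tested) else np.nan,
        "frac_significant_bonferroni": n_sig_adj / len(tested) if len(tested) else np.nan,
        "alpha": config.alpha,
        "bonferroni_m": m,
        "alternative": config.ecm_alternative,
    }
    return {"table": table, "aggregate": aggregate}


# ---------------------------------------------------------------------------
# Dom8: dominance of the minimum eight-way triplet distance
# ---------------------------------------------------------------------------


def eval_dom8(dataset: Dataset, config: EvalConfig) -> dict:
    """Minimum-proportion statistics over homologous locus triplets.

    Cells with total phased reads strictly above ``min_cell_reads`` are
    analyzed; chromosomes are restricted to ``dom8_chromosomes``.  Per
    triplet, the eight three-way distances and min/total proportion; a
    triplet is *dominant* when the proportion is strictly below
    ``dom8_threshold`` (default 0.125/4).
    """
    rows = []
    eligible_cells = []
    for ci, cell in enumerate(dataset):
        if cell.n_reads() <= config.min_cell_reads:
            continue
        eligible_cells.append(cell.cell_id)
        prepped = _preprocess_cell(cell, config)
        binned = bin_cell(prepped, config.resolution)
        chroms = [c for c in config.dom8_chromosomes if c in prepped.autosome_set]
        if len(chroms) < 3:
            continue
        triplets = homologous_triplets(
            binned,
            chroms,
            max_triplets=config.dom8_max_triplets,
            seed=_sub_seed(config, 3, ci),
        )
        for t in triplets:
            rows.append(
                {
                    "cell_id": cell.cell_id,
                    "chrom_1": t.chromosomes[0],
                    "chrom_2": t.chromosomes[1],
                    "chrom_3": t.chromosomes[2],
                    "bin_1": t.bins[0],
                    "bin_2": t.bins[1],
                    "bin_3": t.bins[2],
                    "min_distance": t.minimum,
                    "total_distance": t.total,
                    "min_proportion": t.min_proportion,
                    "dominant": bool(t.min_proportion < config.dom8_threshold),
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        aggregate = {
            "n_eligible_cells": len(eligible_cells),
            "n_triplets": 0,
            "note": "no eligible homologous triplets",
        }
        return {"table": table, "aggregate": aggregate}
    per_cell = table.groupby("cell_id").agg(
        n_triplets=("dominant", "size"),
        n_dominant=("dominant", "sum"),
        min_observed_proportion=("min_proportion", "min"),
    )
    aggregate = {
        "n_eligible_cells": len(eligible_cells),
        "n_triplets": int(len(table)),
        "n_dominant": int(table["dominant"].sum()),
        "min_observed_proportion": float(table["min_proportion"].min()),
        "threshold": config.dom8_threshold,
        "per_cell": per_cell.reset_index().to_dict(orient="records"),
    }
    return {"table": table, "aggregate": aggregate}


# ---------------------------------------------------------------------------
# Salvage: equality of maternal/paternal intra-chromosomal distance matrices
# ---------------------------------------------------------------------------


def _salvage_units(cell: CellMap, config: EvalConfig) -> list[str]:
    counts = cell.phased[cell.phased["chrom"].isin(cell.autosome_set)].groupby("chrom").size()
    if config.salvage_selection == "max_chrom":
        if counts.empty:
            return []
        return [str(counts.idxmax())]
    return sorted(
        (str(c) for c, n in counts.items() if n > config.salvage_min_reads),
        key=_chrom_sort_key,
    )


def eval_salvage_grv(dataset: Dataset, config: EvalConfig) -> dict:
    """GRV + Procrustes tests of maternal vs paternal homolog configurations.

    Per selected (cell, chromosome): bin both homologs, align on shared
    bins (>= ``min_loci`` required), then (a) GRV test on the two
    intra-homolog distance matrices D_MM, D_PP, (b) protest on the aligned
    coordinate configurations, and (c) an intra- vs inter-homolog summary —
    per aligned bin pair (i, j), the ratio of the intra-homolog distance
    ``D(M_i, M_j)`` to the inter-homolog distance ``D(M_i, P_j)``, reported
    as median ratio and the fraction of pairs with intra < inter.

    Verdicts ("similar"/"different") follow ``config.verdict_convention``
    applied at the Bonferroni-adjusted alpha.
    """
    rows = []
    for ci, cell in enumerate(dataset):
        prepped = _preprocess_cell(cell, config)
        binned = bin_cell(prepped, config.resolution)
        for chrom in _salvage_units(prepped, config):
            pair = shared_homolog_bins(binned, chrom)
            base = {"cell_id": cell.cell_id, "chrom": chrom, "n_loci": pair.n}
            if pair.n < config.min_loci:
                rows.append({**base, "skip_reason": f"n < {config.min_loci}"})
                continue
            d_mm = pairwise_distance_matrix(pair.G_M, pair.bin_indices)
            d_pp = pairwise_distance_matrix(pair.G_P, pair.bin_indices)
            seed_g = _sub_seed(config, 4, ci, int(chrom) if chrom.isdigit() else 0, 0)
            seed_p = _sub_seed(config, 4, ci, int(chrom) if chrom.isdigit() else 0, 1)
            grv = grv_test(
                d_mm, d_pp, method=config.grv_method,
                n_perm=config.grv_n_perm, seed=seed_g,
            )
            prot = protest_test(
                pair.G_M, pair.G_P, n_perm=config.protest_n_perm, seed=seed_p
            )
            intra = d_mm.values[np.triu_indices(pair.n, k=1)]
            inter = np.linalg.norm(
                pair.G_M[:, None, :] - pair.G_P[None, :, :], axis=2
            )[np.triu_indices(pair.n, k=1)]
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(inter > 0, intra / inter, np.inf)
            rows.append(
                {
                    **base,
                    "skip_reason": "",
                    "rv": grv.statistic,
                    "grv_p": grv.p_value,
                    "grv_method": grv.method.value,
                    "procrustes_residual": prot.statistic,
                    "protest_p": prot.p_value,
                    "median_intra_inter_ratio": float(np.median(ratio)),
                    "frac_intra_lt_inter": float(np.mean(intra < inter)),
                }
            )
    table = pd.DataFrame(rows)
    tested = table[table["skip_reason"] == ""] if len(table) else table
    m = config.bonferroni_m if config.bonferroni_m is not None else max(len(tested), 1)
    if len(tested):
        grv_adj = np.asarray(bonferroni(list(tested["grv_p"]), m=m))
        prot_adj = np.asarray(bonferroni(list(tested["protest_p"]), m=m))
        table.loc[tested.index, "grv_p_bonferroni"] = grv_adj
        table.loc[tested.index, "protest_p_bonferroni"] = prot_adj
        reject_similar = config.verdict_convention == "reject_means_associated"

        def verdict(adjusted):
            sig = adjusted < config.alpha
            if reject_similar:
                return np.where(sig, "similar", "different")
            return np.where(sig, "different", "similar")

        table.loc[tested.index, "grv_verdict"] = verdict(grv_adj)
        table.loc[tested.index, "protest_verdict"] = verdict(prot_adj)
        tested = table[table["skip_reason"] == ""]
        n_diff_grv = int((tested["grv_verdict"] == "different").sum())
        n_diff_prot = int((tested["protest_verdict"] == "different").sum())
        concord = float((tested["grv_verdict"] == tested["protest_verdict"]).mean())
    else:
        n_diff_grv = n_diff_prot = 0
        concord = np.nan
    aggregate = {
        "n_units": int(len(table)),
        "n_tested": int(len(tested)),
        "n_skipped": int(len(table) - len(tested)),
        "n_different_grv": n_diff_grv,
        "n_different_protest": n_diff_prot,
        "grv_protest_concordance": concord,
        "alpha": config.alpha,
        "bonferroni_m": m,
        "verdict_convention": config.verdict_convention,
        "selection": config.salvage_selection,
    }
    return {"table": table, "aggregate": aggregate}


# ---------------------------------------------------------------------------
# Report runner
# ---------------------------------------------------------------------------

SECTIONS = {
    "dcp": eval_dcp,
    "ecm": eval_ecm,
    "dom8": eval_dom8,
    "salvage": eval_salvage_grv,
}


def run_report(
    dataset: Dataset,
    config: EvalConfig | None = None,
    sections=("dcp", "ecm", "dom8", "salvage"),
    out_dir=None,
    strict: bool = False,
) -> EvalReport:
    """Run the requested evaluation sections and optionally write a bundle.

    Deterministic given the config seed.  A failing section is recorded
    under ``errors`` without aborting the others unless ``strict``.  With
    ``out_dir``, writes ``report.json`` plus one TSV per section table.
    """
    config = config or EvalConfig()
    unknown = set(sections) - set(SECTIONS)
    if unknown:
        raise ValueError(f"unknown sections: {sorted(unknown)}")
    report = EvalReport(config=asdict(config), version=__version__)
    for name in sections:
        try:
            report.sections[name] = SECTIONS[name](dataset, config)
        except Exception as exc:
            if strict:
                raise
            report.errors[name] = f"{type(exc).__name__}: {exc}"
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json())
        for name, sec in report.sections.items():
            sec["table"].to_csv(out / f"{name}.tsv", sep="\t", index=False)
    return report
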