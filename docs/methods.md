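# Methods

## Data model

A read is (cell, chromosome, haplotype ∈ {M, P, unphased}, genomic position
in bp, 3D coordinate in µm). Unphased reads are carried by I/O and excluded
from every analysis. Chromosome labels are opaque strings; sex chromosomes
load but are excluded from the autosome set, and all analyses run on
autosomes (19 for the mouse-like preset, 22 for the human-like one).
Coordinates are treated as micrometres but all statistics depend only on
relative geometry except where rescaling is explicitly applied.

## Preprocessing

**Pronuclear fusion** (zygotes): the paternal cloud is translated so its
centroid coincides with the maternal centroid. Any common target is
equivalent up to a global translation, which no downstream statistic sees.
The procedure is deliberately minimal; it does not model post-fertilization
chromatin reorganization.

**Common-scale rescaling**: each haplotype cloud is scaled about the common
centroid so both RMS radii equal the *geometric mean* of the two original
radii. The geometric mean keeps the total scale change symmetric between
haplotypes; equalizing to either cloud's radius or the arithmetic mean
would be equally defensible, so the choice is documented and the operation
is idempotent. Interphase cells pass through unchanged unless forced.

**Binning**: bins are half-open `[k·r, (k+1)·r)`, 0-based, default
r = 1 Mb (a relaxed 10 Mb option suits sparse data); the per-bin
representative is the unweighted mean of member read coordinates. A
*homologous locus* is a bin holding reads on both haplotypes; shared-bin
alignment takes the sorted intersection of maternal and paternal bin sets.
Binning commutes with rigid motions.

**Filters**: cell-level total-read thresholds (strict `>`, e.g. `>500`) and
per-(chromosome, haplotype) minimum counts (exclusion `<3` applied to the
minimum of the two haplotype counts, since paired analyses need both).
Which predicate defines cell eligibility is configurable and recorded in
reports, as more than one reading is defensible.

## Statistical tests

**RV / GRV.** RV(G_M, G_P) = tr(S_M S_P)/(‖S_M‖_F‖S_P‖_F) with S the
centered Gram matrix, computed either from coordinates or from distance
matrices via S = −½ A D² A (both paths implemented; they agree to 1e−10 and
are cross-checked against an independently coded oracle in the tests). The
GRV test permutes rows and columns of one distance matrix simultaneously:
exact enumeration of all n! permutations for n ≤ 7 (p = count ≥ observed /
n!, ties counted as ≥), otherwise seeded Monte Carlo with the add-one
convention p = (1 + count)/(1 + n_perm), which cannot return 0. A Pearson
type III approximation fitted to the first three permutation-null moments
is provided as an optional fast path. Validation against enumeration shows
tail agreement (p ≤ 0.05) within 0.02, but mid-range p-values can deviate
by up to ~0.15 on near-symmetric configurations at n = 5–7 — a three-moment
continuous fit cannot reproduce a 120-atom discrete null uniformly — so
permutation is the primary inference and the moment fit is never the
default.

**Procrustes / protest.** Reflection-similarity superposition: minimize
‖G̃_P − β G̃_M Z‖_F over orthogonal Z (det −1 admitted) and β > 0, solved by
the SVD of G̃_Mᵀ G̃_P. The reported normalized residual, residual²/‖G̃_P‖²_F
= 1 − tr(Λ)²/(‖G̃_M‖²‖G̃_P‖²), is symmetric in its arguments and equals the
`ss` statistic of vegan's symmetric `procrustes`/`protest` (cross-checked in
the tests). protest permutes the rows of G_P, refits, and counts
permutations with residual ≤ observed, add-one convention.

**Classical tests.** Exact binomial (scipy `binomtest`), Welch t
(unequal-variance default; pooled optional), Bonferroni `min(1, m·p)` with
m always explicit in reports.

**Verdicts.** The GRV and protest nulls are *no association*; rejection is
evidence the two configurations are similar. The default
`verdict_convention="reject_means_associated"` therefore maps a
Bonferroni-significant test to "similar" and a non-significant one to
"different". The opposite mapping (treating rejection as "different"), which
matches how such results are sometimes phrased, is selectable; whichever is
in force is recorded in every report. Note the asymmetry this creates:
"different" is a failure to detect association, so its probability includes
the type II error of the association test, and the attainable "similar"
verdict requires the Bonferroni threshold α/m to exceed the Monte-Carlo
p-value floor 1/(1 + n_perm) — with 999 permutations, more than ~50
simultaneous units saturate the correction and every unit reads
"different". Reports carry n_perm and m so this is visible.

## Evaluation programs

**DCP**: per homolog with a defined centroid whose partner also has one,
the nearest of the other centroids is found; the homolog is flagged when
its partner is the *unique* minimizer (exact distance ties never count;
deterministic label-order tie-breaking). The aggregate flag count over all
per-homolog trials is tested against Binomial(n, p0 = 1/(2K − 1)),
one-sided greater, Bonferroni-corrected over the K chromosomes; the
per-cell "has ≥ 1 flagged chromosome" indicator is reported alongside, as
the trial unit behind the headline counts admits more than one reading.

**ECM**: per cell, group A = homolog-pair centroid distances of eligible
chromosomes (both haplotypes ≥ min reads), group B = all other pairwise
distances among those homolog centroids; Welch t, one-sided by default
(homolog > non-homolog, matching the directional claim being tested; the
sidedness is configurable). Cells without ≥ 2 distances per group are
skipped with a recorded reason. Group sizes (≤ K vs C(2K,2) − K) are
reported because t-test validity at small K matters. *Caveat*: both groups
are functions of the same 2K centroids, so the group means are positively
correlated and the nominal level is conservative — under random territory
placement the measured per-cell rejection rate at α = 0.05 is ≈ 0.035
rather than 0.05 (see the calibration test); a control with independent
draws of the same group sizes calibrates correctly, isolating the shared-
center dependence as the cause.

**Dom8**: cells with total phased reads strictly > 500 are analyzed;
homologous triplets are enumerated across the configured chromosome subset
({1..5} by default) at 1 Mb bins, exhaustively, with an optional seeded
subsampling cap for dense synthetic data. Per triplet the eight three-way
distances (sum of distances of the three chosen points to their centroid)
and min/total proportion; dominance is the *strict* inequality
min_proportion < 0.125/4. The proportion lies in (0, 0.125], with 0.125
attained exactly under uniformity (the total uses compensated summation so
eight equal distances give exactly 1/8).

**Salvage**: chromosome selection per cell by total reads > 500 (mode i)
or the single best-covered chromosome (mode ii); shared-bin pairs need
n ≥ 4 loci (3 is the mathematical minimum; 4 avoids trivially saturated
permutation nulls). Per unit: GRV on D_MM vs D_PP, protest on G_M vs G_P,
and an intra- vs inter-homolog summary (per aligned bin pair (i, j), the
ratio D(M_i, M_j)/D(M_i, P_j), reported as median ratio and the fraction
with intra < inter). Bonferroni over tested units; verdicts per the
convention above, plus GRV/protest concordance.

Failing sections are isolated (recorded under `errors`) unless strict mode
is requested; all aggregates are recomputable from the per-unit tables,
and reports embed the config, seeds and package version.

## Synthetic-data generator

The generator emulates the *statistical geometry* the tests rely on, not
polymer physics (no excluded volume, no loop extrusion).

- **Territories**: 2K centers in a ball of radius `nucleus_radius −
  territory_radius`. RANDOM places them uniformly; ADJACENT_HOMOLOGS places
  maternal centers with enforced spread and each paternal center a small
  offset away (guaranteeing the partner is the nearest center);
  SEPARATED_HOMOLOGS places homolog pairs antipodally. Zygote mode puts all
  maternal territories in one sphere and all paternal in another, centers
  `pronuclear_offset` apart, then scales the paternal side by
  `pronuclear_scale_ratio` about its own centroid.
- **Backbones**: a smoothed 3D random walk (step 0.3 µm, moving-average
  window 5, one vertex per 0.5 Mb) is confined to its territory by leaky
  integration of the walk increments — an Ornstein–Uhlenbeck-style
  restoring force — and scaled to an RMS radius of 0.6 × territory radius.
  Confinement fixes the genomic correlation length
  (`backbone_correlation_mb`, default 1 Mb): positions along the fiber
  decorrelate beyond it. This matters: permutation tests on locus-labelled
  configurations are sensitive to serial correlation, and an *unconfined*
  smooth walk carries territory-scale correlation at every genomic lag,
  making GRV/protest detect "association" between independent homologs the
  vast majority of the time. With 1 Mb decorrelation and the default
  sparsity, ρ = 0 yields Bonferroni-significant similarity on every
  chromosome and ρ = 1 yields a "different" verdict with power ≈ 0.9.
  Real chromatin with strong long-range serial correlation would push these
  tests back toward over-detecting association — a caveat that applies to
  the method itself, not only the simulation.
- **Homolog divergence**: the paternal backbone is the convex blend
  (1 − ρ) × (rigid-motion copy of the maternal backbone) + ρ ×
  (independent backbone). ρ = 0 is an exact Procrustes-equivalence oracle,
  ρ = 1 an independence oracle; RV between binned homolog configurations
  decreases monotonically in ρ.
- **Reads**: Poisson(λ) per homolog at uniform genomic positions
  (independent between homologs, so shared-bin sparsity emerges naturally;
  `shared_read_positions=True` samples both homologs at identical
  positions, which the exact-equivalence tests use because bin means of
  *independently* placed reads differ by within-bin backbone variation even
  at ρ = 0), interpolated along the backbone, plus isotropic Gaussian
  localization noise (default σ = 0.1 µm).
- **Defaults**: mouse-like preset K = 19 with autosome lengths rounded to
  10 Mb and λ = 100 reads per homolog (≈ the zygote median of 3909 phased
  reads over 38 homologs); human-like preset K = 22, λ = 6 (≈ 257 over 44).
- **Reproducibility**: all randomness flows through per-(cell, role,
  chromosome) substreams derived from one seed via `SeedSequence`, so
  adding cells to a cohort never perturbs earlier cells.

What passing tests on this generator do *not* show: robustness to
amplification duplicates, spatially correlated localization error,
non-uniform genomic coverage, or fibers whose serial correlation extends
far beyond 1 Mb — none of which the generator emulates.

## Problem sizes used in the shipped checks

Oracle-agreement checks run at n = 4–6 (50 instances) and 20 Procrustes
pairs against 10,000 random orthogonal candidates; permutation-test
calibration uses n = 15 loci, 1000 replicates × 999 permutations; ECM
calibration uses 1000 simulated cells (400 in the acceptance script, which
also trims calibration to 500 replicates); salvage recovery uses
single-chromosome cohorts of 30–40 cells with λ = 150 (≈ 60 shared 1 Mb
bins). These sizes give Monte-Carlo standard errors comfortably below the
effect sizes being checked.

## Known limitations

- The fusion/rescaling procedure is crude by construction; analyses that
  depend on a common frame (DCP, ECM, the intra-vs-inter summary) inherit
  that crudeness for zygotes. GRV on intra-homolog distance matrices does
  not, which is why the salvage program leans on it.
- The ECM t-test's conservativeness under the null (shared-centroid
  dependence) means its per-cell significance fractions are mildly
  understated everywhere, including on real data.
- The moment-fit GRV path is an approximation with quantified mid-range
  error; use it only where its speed matters and the decision threshold is
  in the tail.
- Bonferroni with many units and few permutations saturates (see Verdicts
  above); raise `grv_n_perm`/`protest_n_perm` or narrow the selection when
  m approaches α(1 + n_perm).
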