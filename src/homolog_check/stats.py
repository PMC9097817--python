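"""Inferential machinery for comparing distance matrices and 3D configurations.

Two complementary notions of similarity between locus-matched maternal and
paternal configurations ``G_M``, ``G_P`` (n x 3):

* **RV coefficient** — a matrix extension of Pearson's correlation,
  ``RV = tr(S_M S_P) / (||S_M||_F ||S_P||_F)`` with ``S = G~ G~^T`` the
  centered Gram matrix.  Since ``S = -1/2 A D^2 A`` (A = I - J/n, D the
  Euclidean distance matrix), RV is completely determined by the two
  intra-homolog distance matrices; both computation paths are implemented
  and must agree.  The **GRV test** assesses association by simultaneous
  row/column permutation of one distance matrix: exact enumeration of all
  n! permutations for small n, seeded Monte Carlo otherwise, and an optional
  Pearson type III approximation fitted to the first three permutation-null
  moments.

* **Procrustes superposition** — least squares over translation, rotation,
  reflection (det Z = -1 admitted: reflection similarity shape) and positive
  scaling.  With centered configurations and SVD ``G~_M^T G~_P = U L V^T``
  the optimum is ``Z = U V^T``, ``beta = tr(L) / ||G~_M||_F^2``; the
  **protest** permutation test relabels the rows of ``G_P`` and compares
  normalized residuals.

Also here: exact binomial test, Welch two-sample t-test and Bonferroni
adjustment, thin wrappers over scipy emitting the same ``TestResult``
records as the permutation tests.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .geometry import DistanceMatrix

__all__ = [
    "TestMethod",
    "TestResult",
    "ProcrustesResult",
    "gram_from_coords",
    "gram_from_distances",
    "rv_coefficient",
    "rv_from_distances",
    "grv_test",
    "procrustes_fit",
    "protest_test",
    "binomial_exact",
    "welch_t",
    "bonferroni",
]

_TOL = 1e-12


class TestMethod(str, enum.Enum):
    PERMUTATION_EXACT = "permutation_exact"
    PERMUTATION_MC = "permutation_mc"
    MOMENT_FIT = "moment_fit"
    CLOSED_FORM = "closed_form"


@dataclass
class TestResult:
    """Universal output of every statistical operation."""

    statistic: float
    p_value: float
    method: TestMethod
    n_permutations: int | str | None = None
    seed: int | None = None
    adjusted_p: float | None = None
    context: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value}")
        if self.adjusted_p is not None and self.adjusted_p < self.p_value - _TOL:
            raise ValueError("adjusted_p must be >= p_value")

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "method": self.method.value,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "adjusted_p": self.adjusted_p,
            **{f"context_{k}": v for k, v in self.context.items()},
        }


@dataclass
class ProcrustesResult:
    """Optimal reflection-similarity superposition of G_M onto G_P."""

    rotation: np.ndarray  # 3x3 orthogonal, det +/-1
    translation: np.ndarray  # 3-vector
    scale: float
    residual: float  # minimized Frobenius criterion value
    normalized_residual: float  # residual^2 / ||centered target||_F^2

    def transform(self, G: np.ndarray) -> np.ndarray:
        """Apply the fitted map ``G -> scale * G Z + translation``."""
        return self.scale * np.asarray(G, float) @ self.rotation + self.translation


# ---------------------------------------------------------------------------
# RV coefficient
# ---------------------------------------------------------------------------


def _centered(G) -> np.ndarray:
    G = np.asarray(G, dtype=float)
    if G.ndim != 2:
        raise ValueError("configuration must be a 2-D array")
    return G - G.mean(axis=0)


def gram_from_coords(G) -> np.ndarray:
    """Centered Gram matrix ``S = G~ G~^T``."""
    Gc = _centered(G)
    return Gc @ Gc.T


def gram_from_distances(D) -> np.ndarray:
    """Centered Gram matrix from a Euclidean distance matrix.

    ``S = -1/2 A D^2 A`` with ``A = I - J/n`` (classical double centering);
    equals ``gram_from_coords`` of any embedding realizing D.
    """
    D = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    D2 = D**2
    row = D2.mean(axis=1, keepdims=True)
    col = D2.mean(axis=0, keepdims=True)
    return -0.5 * (D2 - row - col + D2.mean())


def _rv_from_grams(SM: np.ndarray, SP: np.ndarray) -> float:
    denom = np.linalg.norm(SM) * np.linalg.norm(SP)
    if denom == 0.0:
        raise ValueError("zero-variance configuration: RV undefined")
    return float(np.sum(SM * SP) / denom)


def rv_coefficient(G_M, G_P) -> float:
    """RV matrix correlation between two row-aligned configurations, in [0, 1].

    Invariant to translation, rotation, reflection, and positive scaling of
    either configuration; symmetric in its arguments.
    """
    G_M, G_P = np.asarray(G_M, float), np.asarray(G_P, float)
    if G_M.shape[0] != G_P.shape[0]:
        raise ValueError("configurations must have the same number of rows")
    if G_M.shape[0] < 2:
        raise ValueError("need n >= 2 rows")
    return _rv_from_grams(gram_from_coords(G_M), gram_from_coords(G_P))


def rv_from_distances(D_M, D_P) -> float:
    """RV computed from the two distance matrices via the Gram identity."""
    SM, SP = gram_from_distances(D_M), gram_from_distances(D_P)
    if SM.shape != SP.shape:
        raise ValueError("distance matrices must have matching shape")
    return _rv_from_grams(SM, SP)


# ---------------------------------------------------------------------------
# GRV permutation test
# ---------------------------------------------------------------------------


def _null_stats_exact(SM: np.ndarray, SP: np.ndarray) -> np.ndarray:
    """RV under every simultaneous row/column permutation of S_P.

    Double centering commutes with simultaneous permutation, so permuting
    the distance matrix and recomputing the Gram equals permuting the Gram.
    """
    n = SM.shape[0]
    denom = np.linalg.norm(SM) * np.linalg.norm(SP)
    out = np.empty(math.factorial(n))
    for i, perm in enumerate(itertools.permutations(range(n))):
        ix = np.asarray(perm)
        out[i] = np.sum(SM * SP[np.ix_(ix, ix)]) / denom
    return out


def _null_stats_mc(
    SM: np.ndarray, SP: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    n = SM.shape[0]
    denom = np.linalg.norm(SM) * np.linalg.norm(SP)
    out = np.empty(n_perm)
    for i in range(n_perm):
        ix = rng.permutation(n)
        out[i] = np.sum(SM * SP[np.ix_(ix, ix)]) / denom
    return out


def grv_test(
    D_M,
    D_P,
    method: str | TestMethod = "auto",
    n_perm: int = 999,
    seed: int | None = None,
    exact_limit: int = 7,
) -> TestResult:
    """GRV association test between two distance matrices.

    The statistic is the RV coefficient computed from the distance matrices;
    the null relabels loci by simultaneous row/column permutation of one
    matrix.  ``method``:

    * ``"auto"`` — exact enumeration of all n! permutations when
      ``n <= exact_limit``, otherwise seeded Monte Carlo;
    * ``"permutation_exact"`` / ``"permutation_mc"`` — force a path;
    * ``"moment_fit"`` — Pearson type III fitted to the first three
      permutation-null moments (enumerated when ``n <= exact_limit``, else
      estimated from ``n_perm`` Monte Carlo draws), upper-tail p.

    Exact p-values count ties as >= (``count / n!``); Monte Carlo uses the
    add-one convention ``(1 + count) / (1 + n_perm)``.
    """
    if isinstance(D_M, DistanceMatrix) and isinstance(D_P, DistanceMatrix):
        if D_M.n != D_P.n or not np.array_equal(D_M.labels, D_P.labels):
            raise ValueError("distance matrices must share identical labels")
    SM = gram_from_distances(D_M)
    SP = gram_from_distances(D_P)
    n = SM.shape[0]
    if n < 3:
        raise ValueError("GRV test needs n >= 3 loci")
    if SM.shape != SP.shape:
        raise ValueError("distance matrices must have matching shape")
    observed = _rv_from_grams(SM, SP)

    if method == "auto":
        method = (
            TestMethod.PERMUTATION_EXACT if n <= exact_limit else TestMethod.PERMUTATION_MC
        )
    method = TestMethod(method)

    if method is TestMethod.PERMUTATION_EXACT:
        if n > exact_limit + 1:
            raise ValueError(f"exact enumeration infeasible for n = {n}")
        null = _null_stats_exact(SM, SP)
        p = float(np.mean(null >= observed - _TOL))
        return TestResult(observed, p, method, n_permutations="all", seed=None)

    rng = np.random.default_rng(seed)
    if method is TestMethod.PERMUTATION_MC:
        null = _null_stats_mc(SM, SP, n_perm, rng)
        p = (1.0 + int(np.sum(null >= observed - _TOL))) / (1.0 + n_perm)
        return TestResult(observed, p, method, n_permutations=n_perm, seed=seed)

    if method is TestMethod.MOMENT_FIT:
        if n <= exact_limit:
            null = _null_stats_exact(SM, SP)
            n_used: int | str = "all"
        else:
            null = _null_stats_mc(SM, SP, n_perm, rng)
            n_used = n_perm
        p = _pearson3_upper_tail(null, observed)
        return TestResult(observed, p, method, n_permutations=n_used, seed=seed)

    raise ValueError(f"unsupported GRV method {method}")  # pragma: no cover


def _pearson3_upper_tail(null: np.ndarray, observed: float) -> float:
    """Upper-tail probability of a Pearson type III matched to 3 moments."""
    mean = float(np.mean(null))
    std = float(np.std(null))
    if std == 0.0:
        return 1.0
    skew = float(sps.skew(null))
    p = float(sps.pearson3.sf(observed, skew, loc=mean, scale=std))
    return min(1.0, max(p, 1e-300))


# ---------------------------------------------------------------------------
# Procrustes superposition and protest
# ---------------------------------------------------------------------------


def procrustes_fit(G_M, G_P, with_scaling: bool = True) -> ProcrustesResult:
    """Least-squares reflection-similarity superposition of G_M onto G_P.

    Minimizes ``||G_P - (beta G_M Z + 1 mu^T)||_F`` over orthogonal Z
    (reflections permitted), translation mu, and positive scale beta (fixed
    to 1 when ``with_scaling`` is False).  Closed form via the SVD of
    ``G~_M^T G~_P``.
    """
    G_M, G_P = np.asarray(G_M, float), np.asarray(G_P, float)
    if G_M.shape != G_P.shape or G_M.ndim != 2 or G_M.shape[1] != 3:
        raise ValueError("configurations must be matching (n, 3) arrays")
    n = G_M.shape[0]
    if n < 3:
        raise ValueError("Procrustes fit needs n >= 3 points")
    mean_M, mean_P = G_M.mean(axis=0), G_P.mean(axis=0)
    M, P = G_M - mean_M, G_P - mean_P
    if np.linalg.matrix_rank(M, tol=1e-10) < 2 or np.linalg.matrix_rank(P, tol=1e-10) < 2:
        raise ValueError("degenerate configuration (rank < 2 after centering)")
    U, svals, Vt = np.linalg.svd(M.T @ P)
    Z = U @ Vt
    norm_M2 = float(np.sum(M**2))
    beta = float(np.sum(svals)) / norm_M2 if with_scaling else 1.0
    fitted = beta * M @ Z
    residual = float(np.linalg.norm(P - fitted))
    mu = mean_P - beta * (Z.T @ mean_M)
    norm_P2 = float(np.sum(P**2))
    return ProcrustesResult(
        rotation=Z,
        translation=mu,
        scale=beta,
        residual=residual,
        normalized_residual=residual**2 / norm_P2,
    )


def protest_test(
    G_M, G_P, n_perm: int = 999, seed: int | None = None, with_scaling: bool = True
) -> TestResult:
    """Permutation test of Procrustes concordance (protest).

    The observed statistic is the normalized Procrustes residual; the null
    permutes the rows of ``G_P`` (relabelling loci) and refits.  Small
    residuals indicate concordance, so the p-value counts permutations with
    residual <= observed: ``p = (1 + count) / (1 + n_perm)``.
    """
    observed = procrustes_fit(G_M, G_P, with_scaling).normalized_residual
    rng = np.random.default_rng(seed)
    M, P = _centered(G_M), _centered(G_P)
    norm_M2, norm_P2 = float(np.sum(M**2)), float(np.sum(P**2))
    n = M.shape[0]
    count = 0
    for _ in range(n_perm):
        Pp = P[rng.permutation(n)]
        # permuting rows leaves the column means (zero) unchanged
        tr = float(np.linalg.svd(M.T @ Pp, compute_uv=False).sum())
        if with_scaling:
            stat = 1.0 - tr**2 / (norm_M2 * norm_P2)
        else:
            stat = (norm_P2 + norm_M2 - 2.0 * tr) / norm_P2
        if stat <= observed + _TOL:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return TestResult(observed, p, TestMethod.PERMUTATION_MC, n_permutations=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# Classical tests
# ---------------------------------------------------------------------------

_ALTERNATIVES = {"greater", "less", "two-sided"}


def _norm_alternative(alternative: str) -> str:
    alt = alternative.replace("_", "-")
    if alt not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {sorted(_ALTERNATIVES)}")
    return alt


def binomial_exact(k: int, n: int, p0: float, alternative: str = "greater") -> TestResult:
    """Exact one-sample binomial test of k successes in n trials vs p0."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be in (0, 1)")
    res = sps.binomtest(k, n, p0, alternative=_norm_alternative(alternative))
    return TestResult(
        statistic=float(k),
        p_value=max(float(res.pvalue), 1e-300),
        method=TestMethod.CLOSED_FORM,
        context={"n": n, "p0": p0, "alternative": alternative},
    )


def welch_t(a, b, alternative: str = "two-sided", pooled: bool = False) -> TestResult:
    """Two-sample t-test; Welch (unequal variances) by default."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs >= 2 observations")
    res = sps.ttest_ind(a, b, equal_var=pooled, alternative=_norm_alternative(alternative))
    return TestResult(
        statistic=float(res.statistic),
        p_value=max(float(res.pvalue), 1e-300),
        method=TestMethod.CLOSED_FORM,
        context={
            "n_a": len(a),
            "n_b": len(b),
            "df": float(res.df),
            "alternative": alternative,
            "pooled": pooled,
        },
    )


def bonferroni(p_values, m: int | None = None) -> list[float]:
    """Bonferroni adjustment: ``min(1, m * p)``, order preserving."""
    ps = list(p_values)
    if any(not (0.0 < p <= 1.0) for p in ps):
        raise ValueError("p-values must be in (0, 1]")
    if m is None:
        m = len(ps)
    if m < 1:
        raise ValueError("m must be >= 1")
    return [min(1.0, m * p) for p in ps]
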