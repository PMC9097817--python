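"""RV/GRV, Procrustes/protest, and classical-test behaviour.

Independent oracles used here: a test-local RV-from-distances implementation
with explicit double centering, full n! enumeration via itertools, a
brute-force random-orthogonal-matrix search for the Procrustes optimum, and
scipy.spatial.procrustes as an external cross-check.
"""

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import ortho_group, special_ortho_group

from homolog_check import TestMethod as Method  # avoid Test* collection
from homolog_check import TestResult as Result
from homolog_check import (
    binomial_exact,
    bonferroni,
    grv_test,
    pairwise_distance_matrix,
    procrustes_fit,
    protest_test,
    rv_coefficient,
    rv_from_distances,
    welch_t,
)


# ---------------------------------------------------------------------------
# test-local oracles
# ---------------------------------------------------------------------------


def oracle_rv_from_distances(DM, DP):
    """RV via explicit -1/2 A D^2 A double centering (independent coding)."""

    def gram(D):
        n = D.shape[0]
        A = np.eye(n) - np.ones((n, n)) / n
        return -0.5 * A @ (D**2) @ A

    SM, SP = gram(np.asarray(DM, float)), gram(np.asarray(DP, float))
    return np.trace(SM @ SP) / (np.linalg.norm(SM) * np.linalg.norm(SP))


def oracle_grv_exact_p(DM, DP):
    """Exhaustive n! enumeration, permuting DP's rows and columns."""
    n = DM.shape[0]
    observed = oracle_rv_from_distances(DM, DP)
    count = 0
    for perm in itertools.permutations(range(n)):
        ix = np.asarray(perm)
        stat = oracle_rv_from_distances(DM, DP[np.ix_(ix, ix)])
        if stat >= observed - 1e-12:
            count += 1
    return count / math.factorial(n)


def random_config(rng, n=8):
    return rng.normal(size=(n, 3))


# ---------------------------------------------------------------------------
# RV coefficient
# ---------------------------------------------------------------------------


class TestRV:
    def test_self_association_is_one(self, rng):
        G = random_config(rng)
        assert rv_coefficient(G, G) == pytest.approx(1.0, abs=1e-12)

    def test_similarity_invariance(self, rng):
        G = random_config(rng, 10)
        for Z in (special_ortho_group.rvs(3, random_state=0),
                  -np.eye(3)):  # rotation and point reflection
            H = 2.7 * G @ Z + np.array([1.0, -4.0, 2.0])
            assert rv_coefficient(G, H) == pytest.approx(1.0, abs=1e-10)

    def test_dual_path_agreement(self, rng):
        for _ in range(20):
            GM, GP = random_config(rng, 10), random_config(rng, 10)
            via_coords = rv_coefficient(GM, GP)
            via_dist = rv_from_distances(squareform(pdist(GM)), squareform(pdist(GP)))
            assert via_coords == pytest.approx(via_dist, abs=1e-10)
            assert via_coords == pytest.approx(
                oracle_rv_from_distances(squareform(pdist(GM)), squareform(pdist(GP))),
                abs=1e-10,
            )

    def test_range_and_symmetry(self, rng):
        for _ in range(30):
            GM, GP = random_config(rng, 6), random_config(rng, 6)
            v = rv_coefficient(GM, GP)
            assert -1e-10 <= v <= 1 + 1e-10
            assert v == pytest.approx(rv_coefficient(GP, GM), abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            rv_coefficient(np.zeros((1, 3)), np.zeros((1, 3)))
        with pytest.raises(ValueError):
            rv_coefficient(np.zeros((4, 3)), np.ones((4, 3)))  # zero variance


# ---------------------------------------------------------------------------
# GRV test
# ---------------------------------------------------------------------------


class TestGRV:
    def test_exact_p_matches_enumeration_oracle(self, rng):
        for n in (4, 5):
            for _ in range(5):
                DM = squareform(pdist(random_config(rng, n)))
                DP = squareform(pdist(random_config(rng, n)))
                res = grv_test(DM, DP, method="permutation_exact")
                assert res.p_value == pytest.approx(oracle_grv_exact_p(DM, DP), abs=1e-12)
                assert res.n_permutations == "all"

    def test_identical_matrices_give_minimal_exact_p(self, rng):
        G = random_config(rng, 4)
        D = squareform(pdist(G))
        res = grv_test(D, D, method="permutation_exact")
        # observed = max attainable; p = (#permutations tying the max)/24
        assert res.statistic == pytest.approx(1.0, abs=1e-12)
        assert res.p_value == pytest.approx(oracle_grv_exact_p(D, D), abs=1e-12)

    def test_mc_within_three_standard_errors_of_exact(self, rng):
        """Monte-Carlo p tracks the enumerated p across 50 random instances."""
        n_perm = 5000
        for i, n in enumerate([5] * 20 + [6] * 20 + [7] * 10):
            DM = squareform(pdist(random_config(rng, n)))
            DP = squareform(pdist(random_config(rng, n)))
            p_exact = grv_test(DM, DP, method="permutation_exact").p_value
            p_mc = grv_test(DM, DP, method="permutation_mc", n_perm=n_perm,
                            seed=i).p_value
            se = math.sqrt(p_exact * (1 - p_exact) / n_perm) + 1e-9
            assert abs(p_mc - p_exact) <= 3 * se + 2 / n_perm

    def test_degenerate_equal_statistics_give_p_one(self):
        # equilateral vs equilateral: every relabelling is a symmetry
        angles = [0, 2 * np.pi / 3, 4 * np.pi / 3]
        G = np.array([(np.cos(a), np.sin(a), 0.0) for a in angles])
        D = squareform(pdist(G))
        assert grv_test(D, D, method="permutation_exact").p_value == 1.0

    def test_moment_fit_close_to_exact(self, rng):
        """Pearson type III approximation tracks the enumerated p.

        A three-moment continuous fit cannot reproduce a 120-5040-atom
        discrete null uniformly; the error peaks at mid-range p (~0.45),
        where it can reach ~0.15 on near-symmetric configurations, and is
        small in the tails that matter for testing.  Gate: mean |dp| <= 0.03,
        90th percentile <= 0.06, and tail agreement (p_exact <= 0.05)
        within 0.02."""
        diffs, tail_diffs = [], []
        for n in (5, 6, 7):
            for _ in range(20):
                DM = squareform(pdist(random_config(rng, n)))
                DP = squareform(pdist(random_config(rng, n)))
                p_exact = grv_test(DM, DP, method="permutation_exact").p_value
                p_fit = grv_test(DM, DP, method="moment_fit").p_value
                diffs.append(abs(p_fit - p_exact))
                if p_exact <= 0.05:
                    tail_diffs.append(abs(p_fit - p_exact))
        assert np.mean(diffs) <= 0.03
        assert np.quantile(diffs, 0.9) <= 0.06
        assert tail_diffs and max(tail_diffs) <= 0.02

    def test_label_mismatch_and_small_n_rejected(self, rng):
        G = random_config(rng, 4)
        d1 = pairwise_distance_matrix(G, labels=[0, 1, 2, 3])
        d2 = pairwise_distance_matrix(G, labels=[0, 1, 2, 9])
        with pytest.raises(ValueError):
            grv_test(d1, d2)
        with pytest.raises(ValueError):
            grv_test(np.zeros((2, 2)), np.zeros((2, 2)))

    def test_mc_reproducible_from_seed(self, rng):
        DM = squareform(pdist(random_config(rng, 12)))
        DP = squareform(pdist(random_config(rng, 12)))
        p1 = grv_test(DM, DP, method="permutation_mc", n_perm=99, seed=5).p_value
        p2 = grv_test(DM, DP, method="permutation_mc", n_perm=99, seed=5).p_value
        assert p1 == p2


# ---------------------------------------------------------------------------
# Procrustes
# ---------------------------------------------------------------------------


class TestProcrustes:
    def test_exact_recovery_including_reflection(self, rng):
        for det_sign in (+1, -1):
            GM = random_config(rng, 9)
            Z0 = special_ortho_group.rvs(3, random_state=11)
            if det_sign < 0:
                Z0 = Z0 @ np.diag([1, 1, -1])
            mu0 = np.array([0.5, -1.5, 3.0])
            GP = 2.5 * GM @ Z0 + mu0
            res = procrustes_fit(GM, GP)
            assert res.residual <= 1e-9
            assert res.scale == pytest.approx(2.5, abs=1e-9)
            assert np.allclose(res.rotation.T @ res.rotation, np.eye(3), atol=1e-10)
            np.testing.assert_allclose(res.transform(GM), GP, atol=1e-8)

    def test_mirror_recovered_exactly(self, rng):
        GM = random_config(rng, 7)
        GP = GM * np.array([1.0, 1.0, -1.0])  # reflection only
        res = procrustes_fit(GM, GP)
        assert res.residual <= 1e-9
        assert np.linalg.det(res.rotation) == pytest.approx(-1.0, abs=1e-9)

    def test_closed_form_beats_random_orthogonal_search(self, rng):
        GM, GP = random_config(rng, 8), random_config(rng, 8)
        best = procrustes_fit(GM, GP)
        M = GM - GM.mean(0)
        P = GP - GP.mean(0)
        Zs = ortho_group.rvs(3, size=2000, random_state=17)
        norm_M2 = np.sum(M**2)
        for Z in Zs:
            beta = max(np.trace(Z.T @ M.T @ P) / norm_M2, 0.0)
            assert np.linalg.norm(P - beta * M @ Z) >= best.residual - 1e-12

    def test_matches_scipy_normalized_disparity(self, rng):
        from scipy.spatial import procrustes as scipy_procrustes

        GM, GP = random_config(rng, 10), random_config(rng, 10)
        _, _, disparity = scipy_procrustes(GM, GP)
        # scipy standardizes both configurations; its disparity equals the
        # scaled-fit normalized residual 1 - tr(L)^2/(||M||^2 ||P||^2)
        res = procrustes_fit(GM, GP)
        assert res.normalized_residual == pytest.approx(disparity, abs=1e-10)

    def test_residual_zero_iff_rv_one(self, rng):
        GM = random_config(rng, 8)
        GP = 0.5 * GM @ special_ortho_group.rvs(3, random_state=2) + 1.0
        assert procrustes_fit(GM, GP).residual <= 1e-9
        assert rv_coefficient(GM, GP) >= 1 - 1e-9
        GQ = random_config(rng, 8)
        assert procrustes_fit(GM, GQ).residual > 1e-6
        assert rv_coefficient(GM, GQ) < 1 - 1e-6

    def test_degenerate_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            procrustes_fit(random_config(rng, 2), random_config(rng, 2))
        collinear = np.outer(np.arange(5.0), np.array([1.0, 0, 0]))
        with pytest.raises(ValueError):
            procrustes_fit(collinear, random_config(rng, 5))


class TestProtest:
    def test_rigid_copy_minimal_p(self, rng):
        GM = random_config(rng, 10)
        GP = GM @ special_ortho_group.rvs(3, random_state=4) + 2.0
        res = protest_test(GM, GP, n_perm=999, seed=1)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_seed_reproducible(self, rng):
        GM, GP = random_config(rng, 8), random_config(rng, 8)
        r1 = protest_test(GM, GP, n_perm=199, seed=3)
        r2 = protest_test(GM, GP, n_perm=199, seed=3)
        assert r1.p_value == r2.p_value

    def test_agrees_with_vegan_style_slow_path(self, rng):
        """Fast permutation loop equals refitting procrustes per permutation."""
        GM, GP = random_config(rng, 7), random_config(rng, 7)
        observed = procrustes_fit(GM, GP).normalized_residual
        perm_rng = np.random.default_rng(12)
        count = 0
        n_perm = 200
        for _ in range(n_perm):
            perm = perm_rng.permutation(7)
            if procrustes_fit(GM, GP[perm]).normalized_residual <= observed + 1e-12:
                count += 1
        slow_p = (1 + count) / (1 + n_perm)
        fast = protest_test(GM, GP, n_perm=n_perm, seed=12)
        assert fast.p_value == pytest.approx(slow_p)


# ---------------------------------------------------------------------------
# Classical tests and multiplicity
# ---------------------------------------------------------------------------


class TestClassical:
    def test_binomial_examples(self):
        assert binomial_exact(5, 5, 0.5, "greater").p_value == pytest.approx(0.03125)
        assert binomial_exact(0, 5, 0.5, "greater").p_value == pytest.approx(1.0)
        with pytest.raises(ValueError):
            binomial_exact(6, 5, 0.5)
        with pytest.raises(ValueError):
            binomial_exact(1, 5, 1.0)

    def test_welch_identical_samples(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_welch_matches_hand_formula(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se = math.sqrt(va / len(a) + vb / len(b))
        t = (a.mean() - b.mean()) / se
        df = (va / len(a) + vb / len(b)) ** 2 / (
            (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1)
        )
        from scipy.stats import t as t_dist

        p = 2 * t_dist.sf(abs(t), df)
        res = welch_t(a, b)
        assert res.statistic == pytest.approx(t, abs=1e-12)
        assert res.p_value == pytest.approx(p, abs=1e-12)
        assert res.context["df"] == pytest.approx(df, abs=1e-9)

    def test_welch_power_under_shift(self, rng):
        rejections = 0
        reps = 500
        for _ in range(reps):
            a = rng.normal(1.0, 1.0, 200)
            b = rng.normal(0.0, 1.0, 200)
            rejections += welch_t(a, b, alternative="greater").p_value < 0.05
        assert rejections / reps > 0.9

    def test_bonferroni(self):
        assert bonferroni([0.01, 0.5], m=2) == [0.02, 1.0]
        assert bonferroni([0.3], m=1) == [0.3]
        ps = [0.001, 0.04, 0.2]
        adj = bonferroni(ps)
        assert all(x >= p for x, p in zip(adj, ps))
        with pytest.raises(ValueError):
            bonferroni([0.0])
        with pytest.raises(ValueError):
            bonferroni([1.5])

    def test_result_record_validation(self):
        with pytest.raises(ValueError):
            Result(0.0, 0.0, Method.CLOSED_FORM)
        with pytest.raises(ValueError):
            Result(0.0, 0.5, Method.CLOSED_FORM, adjusted_p=0.1)
        r = Result(1.0, 0.01, Method.CLOSED_FORM, adjusted_p=0.05)
        assert r.to_dict()["adjusted_p"] == 0.05


class TestExternalCrossChecks:
    def test_normalized_residual_matches_vegan_procrustes(self, rng, tmp_path):
        """Symmetric Procrustes sum-of-squares agrees with R vegan."""
        import subprocess

        X, Y = random_config(rng, 9), random_config(rng, 9)
        np.savetxt(tmp_path / "X.csv", X, delimiter=",")
        np.savetxt(tmp_path / "Y.csv", Y, delimiter=",")
        script = (
            'suppressMessages(library(vegan));'
            f'X <- as.matrix(read.csv("{tmp_path}/X.csv", header=FALSE));'
            f'Y <- as.matrix(read.csv("{tmp_path}/Y.csv", header=FALSE));'
            'cat(procrustes(X, Y, symmetric=TRUE)$ss)'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        vegan_ss = float(out.stdout.strip().split()[-1])
        ours = procrustes_fit(X, Y).normalized_residual
        assert ours == pytest.approx(vegan_ss, abs=1e-6)
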