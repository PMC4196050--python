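"""Relationship matrices against independent oracles.

A: Wright's recursive kinship as an independent path to the tabular method.
G: direct element-by-element evaluation of the VanRaden formula.
G_a: an independently solved 2x2 moment system.
H: block-by-block evaluation with explicit inverses.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from onestepblend import (
    GenotypeMatrix,
    adjust_G,
    build_A,
    build_G,
    build_H,
    extract_A22,
    random_pedigree,
    stabilize_G,
)
from onestepblend.popsim import Pedigree, UNKNOWN
from onestepblend.relmat import (
    DegenerateSNPError,
    RelationshipMatrix,
    SingularAdjustmentError,
)


def make_ped(rows):
    df = pd.DataFrame(rows, columns=["animal", "sire", "dam"])
    df["order"] = range(len(df))
    df["genotyped"] = False
    df["cohort"] = "ref_cow"
    df["sex"] = "F"
    return Pedigree(df)


def kinship_oracle(ped: Pedigree) -> np.ndarray:
    """Wright's coefficient of coancestry by memoized recursion; A = 2*phi."""
    sire, dam = ped.parent_indices()
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def phi(i, j):
        if i < 0 or j < 0:
            return 0.0
        if i == j:
            return 0.5 * (1.0 + phi(sire[i], dam[i]))
        if j > i:
            i, j = j, i
        return 0.5 * (phi(sire[i], j) + phi(dam[i], j))

    n = len(ped)
    return np.array([[2.0 * phi(i, j) for j in range(n)] for i in range(n)])


class TestBuildA:
    def test_parent_offspring_base_case(self):
        ped = make_ped([("s", UNKNOWN, UNKNOWN), ("d", UNKNOWN, UNKNOWN), ("o", "s", "d")])
        A = build_A(ped).values
        assert A[0, 2] == A[1, 2] == 0.5
        assert A[2, 2] == 1.0

    def test_full_sibs_and_inbred_offspring(self):
        ped = make_ped(
            [
                ("s", UNKNOWN, UNKNOWN),
                ("d", UNKNOWN, UNKNOWN),
                ("c1", "s", "d"),
                ("c2", "s", "d"),
                ("x", "c1", "c2"),
            ]
        )
        A = build_A(ped).values
        assert A[2, 3] == 0.5  # full sibs
        assert A[4, 4] == 1.25  # F = 0.25 from full-sib mating

    def test_founders_only_identity(self):
        ped = make_ped([(f"f{i}", UNKNOWN, UNKNOWN) for i in range(7)])
        np.testing.assert_array_equal(build_A(ped).values, np.eye(7))

    def test_matches_wright_recursion_on_random_pedigrees(self, rng):
        for _ in range(5):
            ped = random_pedigree(int(rng.integers(10, 60)), rng)
            A = build_A(ped).values
            np.testing.assert_allclose(A, kinship_oracle(ped), atol=1e-12)

    def test_positive_definite(self, rng):
        ped = random_pedigree(80, rng)
        np.linalg.cholesky(build_A(ped).values)  # raises if not PD


class TestExtractA22:
    def test_all_genotyped_is_identity_operation(self, rng):
        ped = random_pedigree(20, rng, genotyped_fraction=1.0)
        A = build_A(ped)
        np.testing.assert_array_equal(extract_A22(A, ped).values, A.values)

    def test_single_genotyped_founder(self):
        ped = make_ped([("f", UNKNOWN, UNKNOWN)])
        ped.records.loc[0, "genotyped"] = True
        A = build_A(ped)
        np.testing.assert_array_equal(extract_A22(A, ped).values, [[1.0]])

    def test_equals_brute_force_selection(self, rng):
        ped = random_pedigree(5, rng, n_founders=2, genotyped_fraction=0.6)
        A = build_A(ped)
        A22 = extract_A22(A, ped)
        mask = ped.records["genotyped"].to_numpy(bool)
        expected = A.values[mask][:, mask]
        np.testing.assert_array_equal(A22.values, expected)


class TestBuildG:
    def test_toy_matrix_against_direct_formula(self, rng):
        counts = rng.integers(0, 3, size=(3, 5)).astype(float)
        freqs = rng.uniform(0.1, 0.9, 5)
        G = build_G([f"a{i}" for i in range(3)], counts, freqs).values
        # independent element-by-element evaluation
        denom = 2 * np.sum(freqs * (1 - freqs))
        expected = np.empty((3, 3))
        for i in range(3):
            for j in range(3):
                zi = counts[i] - 2 * freqs
                zj = counts[j] - 2 * freqs
                expected[i, j] = float(np.dot(zi, zj)) / denom
        np.testing.assert_allclose(G, expected, atol=1e-12)

    def test_identical_rows_identical_entries(self):
        counts = np.array([[0, 1, 2, 1], [0, 1, 2, 1]], dtype=float)
        freqs = np.array([0.3, 0.5, 0.6, 0.4])
        G = build_G(["a", "b"], counts, freqs).values
        assert G[0, 0] == pytest.approx(G[1, 1]) == pytest.approx(G[0, 1])

    def test_degenerate_frequency_raises(self):
        with pytest.raises(DegenerateSNPError):
            build_G(["a", "b"], np.zeros((2, 2)), np.array([0.0, 0.5]))


class TestAdjustG:
    def test_identity_when_G_equals_A22(self, rng):
        ped = random_pedigree(30, rng, genotyped_fraction=1.0)
        A = build_A(ped)
        A22 = extract_A22(A, ped)
        G = RelationshipMatrix(A22.animal_ids, A22.values.copy(), "G")
        Ga, adj = adjust_G(G, A22)
        assert adj.beta == pytest.approx(1.0, abs=1e-12)
        assert adj.alpha == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(Ga.values, G.values, atol=1e-12)

    def test_against_independent_linear_solver(self):
        # moments fixed: beta, alpha from an explicit 2x2 solve
        dG, oG, dA, oA = 1.2, 0.1, 1.05, 0.02
        n = 4
        ids = [f"a{i}" for i in range(n)]
        G = np.full((n, n), oG)
        np.fill_diagonal(G, dG)
        A22 = np.full((n, n), oA)
        np.fill_diagonal(A22, dA)
        _, adj = adjust_G(
            RelationshipMatrix(ids, G, "G"), RelationshipMatrix(ids, A22, "A22")
        )
        beta_exp, alpha_exp = np.linalg.solve([[dG, 1], [oG, 1]], [dA, oA])
        assert adj.beta == pytest.approx(beta_exp, rel=1e-12)
        assert adj.alpha == pytest.approx(alpha_exp, rel=1e-12)

    @given(st.integers(min_value=0, max_value=10_000))
    def test_moment_identity_holds_on_arbitrary_input(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 12))
        M = rng.normal(size=(n, n))
        G = RelationshipMatrix([f"x{i}" for i in range(n)], M @ M.T / n + np.eye(n), "G")
        ped = random_pedigree(n, rng, genotyped_fraction=1.0)
        A22v = build_A(ped).values
        A22 = RelationshipMatrix(G.animal_ids, A22v, "A22")
        Ga, adj = adjust_G(G, A22)
        off = ~np.eye(n, dtype=bool)
        assert abs(np.diag(Ga.values).mean() - np.diag(A22v).mean()) < 1e-10
        assert abs(Ga.values[off].mean() - A22v[off].mean()) < 1e-10

    def test_singular_moment_system_raises(self):
        ids = ["a", "b"]
        M = np.full((2, 2), 1.0)
        with pytest.raises(SingularAdjustmentError):
            adjust_G(RelationshipMatrix(ids, M, "G"), RelationshipMatrix(ids, M, "A22"))


class TestBuildH:
    def test_collapse_when_G_is_A22(self, rng):
        ped = random_pedigree(50, rng)
        A = build_A(ped)
        A22 = extract_A22(A, ped)
        G = RelationshipMatrix(A22.animal_ids, A22.values.copy(), "G")
        H = build_H(A, G, ped)
        np.testing.assert_allclose(H.values, A.values, atol=1e-10)

    def test_unrelated_nongenotyped_row_unchanged(self):
        # z unrelated to both genotyped animals: its H row must equal its A row
        ped = make_ped(
            [("a", UNKNOWN, UNKNOWN), ("b", UNKNOWN, UNKNOWN), ("z", UNKNOWN, UNKNOWN)]
        )
        ped.records.loc[:1, "genotyped"] = True
        A = build_A(ped)
        G = RelationshipMatrix(["a", "b"], np.array([[1.1, 0.3], [0.3, 0.9]]), "G")
        H = build_H(A, G, ped)
        iz = H.index_of(["z"])[0]
        np.testing.assert_allclose(H.values[iz], A.values[iz], atol=1e-14)

    def test_four_animal_block_oracle(self):
        # 2 genotyped, 2 not; independent evaluation with explicit inverses
        ped = make_ped(
            [
                ("s", UNKNOWN, UNKNOWN),
                ("d", UNKNOWN, UNKNOWN),
                ("o1", "s", "d"),
                ("o2", "s", "d"),
            ]
        )
        ped.records.loc[[2, 3], "genotyped"] = True
        A = build_A(ped)
        Gv = np.array([[1.05, 0.45], [0.45, 0.98]])
        G = RelationshipMatrix(["o1", "o2"], Gv, "G")
        H = build_H(A, G, ped)

        Av = A.values
        n_idx, g_idx = [0, 1], [2, 3]
        A11 = Av[np.ix_(n_idx, n_idx)]
        A12 = Av[np.ix_(n_idx, g_idx)]
        A22i = np.linalg.inv(Av[np.ix_(g_idx, g_idx)])
        H11 = A11 + A12 @ A22i @ (Gv - Av[np.ix_(g_idx, g_idx)]) @ A22i @ A12.T
        H12 = A12 @ A22i @ Gv
        expected = np.block([[H11, H12], [H12.T, Gv]])
        got = H.values[np.ix_(n_idx + g_idx, n_idx + g_idx)]
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_H22_equals_G_exactly(self, small_population):
        ped, geno, _ = small_population
        A = build_A(ped)
        G = build_G(geno=geno)
        H = build_H(A, G, ped)
        gidx = H.index_of(ped.genotyped_ids)
        np.testing.assert_array_equal(H.values[np.ix_(gidx, gidx)], G.values)

    def test_symmetry(self, small_population):
        ped, geno, _ = small_population
        H = build_H(build_A(ped), build_G(geno=geno), ped)
        assert np.abs(H.values - H.values.T).max() < 1e-12


class TestGConvergesToA22:
    def test_mean_deviation_decreases_with_snp_count(self):
        """With unlinked SNPs, G estimates A22; its element-wise deviation
        shrinks as markers accumulate."""
        from onestepblend import SimConfig, simulate_genotypes, simulate_pedigree

        devs = []
        for n_snps in (500, 2000, 8000):
            vals = []
            for seed in (1, 2):
                cfg = SimConfig(
                    n_sires=4, n_ref_cows=30, n_val_cows=10, n_dams_nongeno=5,
                    n_halfsibs_per_sire=2, n_snps=n_snps, n_qtl=10, seed=seed,
                )
                ped = simulate_pedigree(cfg)
                geno = simulate_genotypes(ped, cfg)
                A22 = extract_A22(build_A(ped), ped)
                G = build_G(geno=geno)
                vals.append(np.abs(G.values - A22.values).mean())
            devs.append(np.mean(vals))
        assert devs[0] > devs[1] > devs[2]


def test_stabilize_blends_toward_A22(rng):
    ped = random_pedigree(20, rng, genotyped_fraction=1.0)
    A22 = extract_A22(build_A(ped), ped)
    G = RelationshipMatrix(A22.animal_ids, A22.values + 0.2 * np.eye(20), "G")
    Gs = stabilize_G(G, A22, weight=0.95)
    np.testing.assert_allclose(Gs.values, 0.95 * G.values + 0.05 * A22.values)
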