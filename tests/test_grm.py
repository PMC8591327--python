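import numpy as np
import pytest

from hetocs import (
    build_relationship_set,
    coancestry,
    compute_adjusted_grm,
    compute_grm,
    compute_het_hom_counts,
    encode_genotypes,
    het_hom_vectors,
    project_pd,
)
from hetocs.popgen import GenotypeMatrix

from conftest import MICRO_X, panel_from_X, random_panel


def naive_grm_and_counts(X: np.ndarray):
    """O(N^2 L) per-pair per-locus oracle for G and Q."""
    L, N = X.shape
    G = np.zeros((N, N))
    Q = np.zeros((N, N))
    for i in range(N):
        for j in range(N):
            for l in range(L):
                a, b = X[l, i], X[l, j]
                G[i, j] += a * b
                if i != j and ((a == 0) != (b == 0)):
                    Q[i, j] += 1
    return G, Q


class TestPairValues:
    @pytest.mark.parametrize(
        "a,b,g_val,q_val",
        [(1, 1, 1, 0), (-1, -1, 1, 0), (1, -1, -1, 0), (0, 1, 0, 1),
         (0, -1, 0, 1), (0, 0, 0, 0)],
    )
    def test_single_locus_pair_semantics(self, a, b, g_val, q_val):
        X = GenotypeMatrix(np.array([[a, b]]))
        assert compute_grm(X)[0, 1] == g_val
        assert compute_het_hom_counts(X)[0, 1] == q_val

    def test_identical_full_homozygotes(self):
        X = GenotypeMatrix(np.ones((7, 2), dtype=int))
        assert compute_grm(X)[0, 1] == 7
        assert compute_het_hom_counts(X)[0, 1] == 0

    def test_full_het_vs_full_hom(self):
        X = GenotypeMatrix(np.column_stack([np.zeros(5, int), np.ones(5, int)]))
        assert compute_het_hom_counts(X)[0, 1] == 5


class TestMicroFixture:
    def test_exact_integer_matrices(self, micro_panel):
        X = encode_genotypes(micro_panel)
        G = compute_grm(X)
        Q = compute_het_hom_counts(X)
        assert np.array_equal(
            G, np.array([[3, 0, 0], [0, 2, -1], [0, -1, 3]], dtype=float)
        )
        assert np.array_equal(
            Q, np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        )

    @pytest.mark.parametrize(
        "beta,checks",
        [
            (0.0, {(0, 1): 0.0, (1, 2): -1.0}),
            (0.5, {(0, 1): 0.5, (0, 2): 1.0, (1, 2): 0.5}),
            (-0.5, {(1, 2): -2.5}),
        ],
    )
    def test_adjusted_matrix(self, micro_panel, beta, checks):
        X = encode_genotypes(micro_panel)
        Gs = compute_adjusted_grm(
            compute_grm(X), compute_het_hom_counts(X), beta
        )
        for (i, j), v in checks.items():
            assert Gs[i, j] == pytest.approx(v)

    def test_beta_out_of_range(self, micro_panel):
        X = encode_genotypes(micro_panel)
        with pytest.raises(ValueError):
            compute_adjusted_grm(compute_grm(X), compute_het_hom_counts(X), 1.5)

    def test_het_hom_vectors_and_identity(self, micro_panel):
        X = encode_genotypes(micro_panel)
        c = np.full(3, 1 / 3)
        hh = het_hom_vectors(X, c)
        assert np.allclose(hh.He + hh.Ho, 1.0)
        assert np.allclose(hh.He * hh.Ho, [2 / 9, 0, 2 / 9, 2 / 9])
        assert (hh.He * hh.Ho).sum() == pytest.approx(2 / 3)
        Q = compute_het_hom_counts(X)
        assert c @ Q @ c == pytest.approx(4 / 3)
        assert c @ Q @ c == pytest.approx(2 * hh.He @ hh.Ho)

    def test_coancestry_normalized(self, micro_panel):
        X = encode_genotypes(micro_panel)
        G = compute_grm(X)
        c = np.full(3, 1 / 3)
        assert coancestry(c, G, n_loci=4) == pytest.approx(1 / 6)
        assert coancestry(c, G, normalized=False) == pytest.approx(2 / 3)


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        n, L = int(rng.integers(3, 10)), int(rng.integers(5, 50))
        panel = random_panel(n, L, seed=seed + 100)
        X = encode_genotypes(panel)
        G, Q = compute_grm(X), compute_het_hom_counts(X)
        G0, Q0 = naive_grm_and_counts(X.X)
        assert np.allclose(G, G0)
        assert np.allclose(Q, Q0)

    def test_diag_counts_homozygous_loci(self):
        panel = random_panel(6, 20, seed=9)
        X = encode_genotypes(panel)
        G = compute_grm(X)
        for i in range(6):
            h1, h2 = panel.haplotypes_of(i)
            assert G[i, i] == np.sum(h1 == h2)

    def test_permutation_equivariance(self):
        panel = random_panel(7, 15, seed=10)
        X = encode_genotypes(panel).X
        perm = np.random.default_rng(0).permutation(7)
        Xp = GenotypeMatrix(X[:, perm])
        for f in (compute_grm, compute_het_hom_counts):
            M = f(GenotypeMatrix(X))
            assert np.allclose(f(Xp), M[np.ix_(perm, perm)])


class TestDecomposition:
    @pytest.mark.parametrize("beta", [-1.0, -0.5, 0.3, 1.0])
    def test_quadratic_form_identity(self, beta):
        rng = np.random.default_rng(17)
        panel = random_panel(12, 40, seed=18)
        X = encode_genotypes(panel)
        rel = build_relationship_set(X, beta)
        c = rng.dirichlet(np.ones(12))
        lhs = c @ rel.Gstar @ c
        rhs = c @ rel.G @ c + beta * (c @ rel.Q @ c)
        assert lhs == pytest.approx(rhs, abs=1e-10)
        hh = het_hom_vectors(X, c)
        assert c @ rel.Q @ c == pytest.approx(2 * hh.He @ hh.Ho, abs=1e-10)


class TestPdProjection:
    def test_pd_input_unchanged(self):
        M = np.diag([3.0, 2.0, 1.0])
        assert np.allclose(project_pd(M, 1e-8), M)

    def test_indefinite_two_by_two_limit(self):
        # eigenvalues 3 and -1; clipping -1 toward 0 gives the rank-1 limit
        M = np.array([[1.0, 2.0], [2.0, 1.0]])
        P = project_pd(M, 1e-12)
        assert np.allclose(P, [[1.5, 1.5], [1.5, 1.5]], atol=1e-6)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        M = rng.normal(size=(6, 6))
        M = (M + M.T) / 2
        P1 = project_pd(M, 1e-6)
        assert np.allclose(project_pd(P1, 1e-6), P1, atol=1e-10)

    def test_spectral_distance_and_floor(self):
        rng = np.random.default_rng(4)
        M = rng.normal(size=(8, 8))
        M = (M + M.T) / 2
        floor = 1e-4
        P = project_pd(M, floor)
        lam_in = np.linalg.eigvalsh(M)
        lam_out = np.linalg.eigvalsh(P)
        assert lam_out[0] >= floor - 1e-12
        dist = np.linalg.norm(P - M, ord=2)
        assert dist == pytest.approx(max(0.0, floor - lam_in[0]), abs=1e-8)

    def test_kept_eigenvalues_not_decreased(self):
        rng = np.random.default_rng(5)
        M = rng.normal(size=(6, 6))
        M = (M + M.T) / 2
        floor = 0.05
        lam_in = np.sort(np.linalg.eigvalsh(M))
        lam_out = np.sort(np.linalg.eigvalsh(project_pd(M, floor)))
        kept = lam_in[lam_in >= floor]
        assert np.allclose(lam_out[-kept.size:], kept, atol=1e-8)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            project_pd(np.array([[np.nan, 0.0], [0.0, 1.0]]), 1e-8)


def test_relationship_set_consistency(micro_panel):
    X = encode_genotypes(micro_panel)
    rel = build_relationship_set(X, beta=-0.5)
    assert np.allclose(rel.Gstar, rel.G - 0.5 * rel.Q)
    assert np.all(np.diag(rel.Q) == 0)
    assert np.linalg.eigvalsh(rel.Gstar_pd)[0] >= rel.eig_floor - 1e-12
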