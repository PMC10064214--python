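"""Relationship matrices: A/A⁻¹ with UPGs, Γ, A^Γ, G^Γ, H^Γ⁻¹.

Every sparse builder is checked against an independent dense oracle
(tabular-method relationship matrix + dense inversion) on small pedigrees.
"""

import numpy as np
import pytest

from beefgs import relationships as rel
from tests.conftest import random_pedigree


def dense_tabular_a(sire, dam):
    """Independent oracle: textbook tabular method."""
    n = len(sire)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
        for j in range(i):
            a = 0.0
            if s >= 0:
                a += 0.5 * A[j, s]
            if d >= 0:
                a += 0.5 * A[j, d]
            A[i, j] = A[j, i] = a
    return A


def dense_tabular_a_gamma(sire, dam, breed, gamma):
    """Oracle: tabular method with the metafounder block initialised to Γ."""
    m = gamma.shape[0]
    n = len(sire)
    A = np.zeros((m + n, m + n))
    A[:m, :m] = gamma
    for i in range(n):
        s = sire[i] + m if sire[i] >= 0 else breed[i]
        d = dam[i] + m if dam[i] >= 0 else breed[i]
        r = i + m
        for j in range(r):
            A[r, j] = A[j, r] = 0.5 * (A[s, j] + A[d, j])
        A[r, r] = 1.0 + 0.5 * A[s, d]
    return A


class TestAInverse:
    def test_trio_pattern(self):
        """Child of two unrelated non-inbred parents: the classic
        (2, -1, -1) row pattern and unit diagonal relationship."""
        sire = np.array([-1, -1, 0])
        dam = np.array([-1, -1, 1])
        ainv = rel.a_inverse(sire, dam).toarray()
        assert ainv[2, 2] == pytest.approx(2.0)
        assert ainv[2, 0] == ainv[2, 1] == pytest.approx(-1.0)
        A = dense_tabular_a(sire, dam)
        assert A[2, 2] == pytest.approx(1.0)

    def test_full_sib_mating_inbreeding(self):
        sire = np.array([-1, -1, 0, 0, 2])
        dam = np.array([-1, -1, 1, 1, 3])
        f = rel.inbreeding(sire, dam)
        assert f[4] == pytest.approx(0.25)

    def test_random_pedigree_matches_dense_inverse(self, rng):
        sire, dam, _, _ = random_pedigree(50, 6, rng)
        A = dense_tabular_a(sire, dam)
        ainv = rel.a_inverse(sire, dam).toarray()
        assert np.abs(ainv - np.linalg.inv(A)).max() < 1e-8

    def test_unordered_pedigree_rejected(self):
        with pytest.raises(ValueError, match="topologically"):
            rel.a_inverse(np.array([1, -1]), np.array([-1, -1]))

    def test_colleau_submatrix_matches_tabular(self, rng):
        sire, dam, _, _ = random_pedigree(80, 8, rng)
        idx = np.array([3, 20, 40, 79])
        A = dense_tabular_a(sire, dam)
        assert np.abs(rel.a_submatrix(sire, dam, idx)
                      - A[np.ix_(idx, idx)]).max() < 1e-10


class TestUPGInverse:
    def test_q_matrix_rows_sum_to_one(self, rng):
        sire, dam, _, breed = random_pedigree(40, 6, rng, n_breeds=2)
        pms = rel.build_a_inverse_upg(sire, dam, breed, 2)
        np.testing.assert_allclose(pms.q.sum(axis=1), 1.0)
        assert np.all((pms.q >= 0) & (pms.q <= 1))

    def test_pure_breeding_q_is_breed_indicator(self, rng):
        sire, dam, _, breed = random_pedigree(40, 6, rng, n_breeds=2)
        pms = rel.build_a_inverse_upg(sire, dam, breed, 2)
        np.testing.assert_allclose(pms.q[np.arange(40), breed], 1.0)

    def test_grouped_inverse_block_structure(self, rng):
        """The animal block of the grouped inverse equals plain A⁻¹."""
        sire, dam, _, breed = random_pedigree(30, 4, rng, n_breeds=2)
        pms = rel.build_a_inverse_upg(sire, dam, breed, 2)
        plain = rel.a_inverse(sire, dam).toarray()
        grouped = pms.a_inv.toarray()
        np.testing.assert_allclose(grouped[:30, :30], plain, atol=1e-12)


class TestGamma:
    def test_hand_computed_scaling(self):
        """A frequency column with variance 0.03125 gives γ = 0.25.

        Frequencies (0.25, 0.5): mean 0.375, squared deviations 1/64 + 1/64
        divided by (n-1)=1 gives 1/32 = 0.03125, and 8/32 = 0.25.
        """
        P = np.array([[0.25], [0.5]])
        assert np.var(P[:, 0], ddof=1) == pytest.approx(0.03125)
        g = rel.gamma_from_freqs(P)
        assert g[0, 0] == pytest.approx(0.25)

    def test_four_marker_two_breed_hand_case(self):
        """Γ = 8·Cov(P) on a 4-marker, 2-breed table, against hand algebra."""
        P = np.array([[0.2, 0.3], [0.4, 0.5], [0.6, 0.5], [0.8, 0.7]])
        C = np.cov(P, rowvar=False, ddof=1)
        g = rel.gamma_from_freqs(P)
        np.testing.assert_allclose(g, 8 * C)
        # hand check of one entry: cov of (0.2,0.4,0.6,0.8) and
        # (0.3,0.5,0.5,0.7): deviations (-0.3,-0.1,0.1,0.3)/(-0.2,0,0,0.2)
        # -> sum 0.12, /3 = 0.04 -> gamma_12 = 0.32
        assert g[0, 1] == pytest.approx(0.32)

    def test_constant_frequencies_give_zero(self):
        P = np.full((10, 3), 0.5)
        np.testing.assert_allclose(rel.gamma_from_freqs(P), 0.0)

    def test_allele_relabelling_invariance(self, rng):
        P = rng.random((20, 4))
        np.testing.assert_allclose(rel.gamma_from_freqs(P),
                                   rel.gamma_from_freqs(1.0 - P))

    def test_too_few_markers_rejected(self):
        with pytest.raises(ValueError, match="two markers"):
            rel.gamma_from_freqs(np.array([[0.5, 0.4]]))

    def test_psd_repair_clips_negatives(self):
        g = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.warns(UserWarning, match="clipping"):
            g2 = rel.make_psd(g)
        w = np.linalg.eigvalsh(g2)
        assert w.min() >= -1e-12


class TestAGamma:
    def test_metafounder_child_diagonal(self):
        """γ = 0.5 metafounder: its immediate offspring has diagonal 1.25."""
        g = np.array([[0.5]])
        A = rel.a_gamma_dense([-1], [-1], [0], g)
        assert A[1, 1] == pytest.approx(1.25)

    def test_gamma_zero_reduces_to_classical_a(self, rng):
        sire, dam, _, breed = random_pedigree(30, 4, rng, n_breeds=2)
        AG = rel.a_gamma_dense(sire, dam, breed, np.zeros((2, 2)))
        np.testing.assert_allclose(AG[2:, 2:], dense_tabular_a(sire, dam))

    def test_sparse_inverse_matches_dense_oracle(self, rng):
        sire, dam, _, breed = random_pedigree(30, 6, rng, n_breeds=3)
        gamma = np.array([[0.5, 0.2, 0.1], [0.2, 0.6, 0.15], [0.1, 0.15, 0.4]])
        AG = dense_tabular_a_gamma(sire, dam, breed, gamma)
        m = 3
        perm = list(range(m, m + 30)) + list(range(m))
        gp = rel.build_a_gamma_inverse(sire, dam, breed, gamma)
        err = np.abs(gp.a_gamma_inv.toarray()
                     - np.linalg.inv(AG[np.ix_(perm, perm)])).max()
        assert err < 1e-8

    def test_subset_matches_dense_oracle(self, rng):
        sire, dam, _, breed = random_pedigree(40, 6, rng, n_breeds=3)
        gamma = 0.4 * np.eye(3) + 0.1
        AG = dense_tabular_a_gamma(sire, dam, breed, gamma)
        idx = np.array([5, 17, 23, 39])
        sub = rel.a_gamma_submatrix(sire, dam, breed, gamma, idx)
        np.testing.assert_allclose(sub, AG[np.ix_(idx + 3, idx + 3)],
                                   atol=1e-10)


class TestGGamma:
    def test_all_heterozygous_animal_has_zero_diagonal(self):
        dos = np.full((1, 10), 1)
        G = rel.build_g_gamma(dos)
        assert G[0, 0] == 0.0

    def test_hand_computed_two_marker_case(self):
        """Genotypes (AA, aa): w = (1, -1), s = 1, self-relationship 2."""
        dos = np.array([[2, 0]])
        G = rel.build_g_gamma(dos)
        assert G[0, 0] == pytest.approx(2.0)

    def test_identical_twins_relationship_equals_diagonal(self, rng):
        row = rng.integers(0, 3, 30)
        dos = np.stack([row, row])
        G = rel.build_g_gamma(dos)
        assert G[0, 1] == pytest.approx(G[0, 0]) == pytest.approx(G[1, 1])

    def test_invalid_dosages_rejected(self):
        with pytest.raises(ValueError, match="dosages"):
            rel.build_g_gamma(np.array([[3, 0]]))


class TestHGammaInverse:
    @pytest.fixture()
    def toy(self, rng):
        sire, dam, _, breed = random_pedigree(40, 6, rng, n_breeds=2)
        gamma = np.array([[0.5, 0.2], [0.2, 0.6]])
        gp = rel.build_a_gamma_inverse(sire, dam, breed, gamma)
        geno = np.sort(rng.choice(40, 12, replace=False))
        dos = rng.integers(0, 3, (12, 60))
        G = rel.build_g_gamma(dos)
        a22 = rel.a_gamma_submatrix(sire, dam, breed, gamma, geno)
        return sire, dam, breed, gamma, gp, geno, G, a22

    def test_matches_dense_assembly(self, toy):
        sire, dam, breed, gamma, gp, geno, G, a22 = toy
        h = rel.build_h_gamma_inverse(gp.a_gamma_inv, a22, G, geno)
        AG = dense_tabular_a_gamma(sire, dam, breed, gamma)
        m = 2
        perm = list(range(m, m + 40)) + list(range(m))
        Hd = np.linalg.inv(AG[np.ix_(perm, perm)])
        Hd[np.ix_(geno, geno)] += np.linalg.inv(G) - np.linalg.inv(a22)
        assert np.abs(h.to_dense() - Hd).max() < 1e-8

    def test_zero_genotyped_reduces_to_pedigree(self, toy):
        gp = toy[4]
        h = rel.build_h_gamma_inverse(gp.a_gamma_inv, None, None,
                                      np.array([], dtype=int))
        assert h.correction is None
        np.testing.assert_allclose(h.to_dense(), gp.a_gamma_inv.toarray())

    def test_g_equal_a22_gives_zero_correction(self, toy):
        sire, dam, breed, gamma, gp, geno, G, a22 = toy
        h = rel.build_h_gamma_inverse(gp.a_gamma_inv, a22, a22.copy(), geno)
        assert np.abs(h.correction).max() < 1e-8

    def test_matvec_agrees_with_dense(self, toy, rng):
        sire, dam, breed, gamma, gp, geno, G, a22 = toy
        h = rel.build_h_gamma_inverse(gp.a_gamma_inv, a22, G, geno)
        x = rng.normal(size=h.dim)
        np.testing.assert_allclose(h.matvec(x), h.to_dense() @ x, atol=1e-10)
        np.testing.assert_allclose(h.diagonal(), np.diag(h.to_dense()),
                                   atol=1e-10)


class TestGenomicPedigreeAgreement:
    def test_g_tracks_a_under_complete_genotyping(self, micro_pop):
        """With every candidate genotyped, G^Γ off-diagonals correlate
        strongly with the pedigree counterpart A22^Γ."""
        pop = micro_pop["pop"]
        gmap = micro_pop["gmap"]
        sire = np.where(pop.sire >= 0, pop.sire, -1)
        dam = np.where(pop.dam >= 0, pop.dam, -1)
        base = np.flatnonzero(pop.gen == 0)
        markers = gmap.marker_idx
        P = np.stack([
            pop.haplo[base[pop.breed[base] == b]][:, :, markers].mean(axis=(0, 1))
            for b in range(5)], axis=1)
        gamma = rel.gamma_from_freqs(P)
        cand = np.flatnonzero(pop.gen == pop.gen.max())[:150]
        G = rel.build_g_gamma(pop.dosage(markers, rows=cand))
        A22 = rel.a_gamma_submatrix(sire, dam, pop.breed, gamma, cand)
        iu = np.triu_indices(cand.size, 1)
        r = np.corrcoef(G[iu], A22[iu])[0, 1]
        assert r > 0.6  # micro genome has only 120 markers; desk exceeds 0.8
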