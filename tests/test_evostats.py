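import numpy as np
import pytest

from pepcore.evostats import (
    BackgroundFrequencies,
    CouplingMatrix,
    FrequencyProfile,
    background_frequencies,
    conservation,
    coupling_matrix,
    coupling_pcc,
    flat_pcc,
    joint_frequencies,
    positional_weights,
    site_frequencies,
)
from pepcore.peptide_io import ALPHABET, PeptideAlignment, encode_alignment

from conftest import random_alignment

A20 = len(ALPHABET)


# ---------------------------------------------------------------------------
# brute-force oracles: naive loops, no shared code with the implementation
# ---------------------------------------------------------------------------

def oracle_site_freq(aln, pc):
    f = np.zeros((aln.L, A20))
    for seq in aln.sequences:
        for i, ch in enumerate(seq):
            f[i, ALPHABET.index(ch)] += 1
    return (1 - pc) * f / aln.M + pc / A20


def oracle_joint_freq(aln, pc):
    fj = np.zeros((aln.L, A20, aln.L, A20))
    for seq in aln.sequences:
        for i, ci in enumerate(seq):
            for j, cj in enumerate(seq):
                fj[i, ALPHABET.index(ci), j, ALPHABET.index(cj)] += 1
    fj /= aln.M
    out = np.zeros_like(fj)
    for i in range(aln.L):
        for j in range(aln.L):
            for a in range(A20):
                for b in range(A20):
                    if i == j:
                        if a == b:
                            out[i, a, j, b] = (1 - pc) * fj[i, a, j, b] + pc / A20
                    else:
                        out[i, a, j, b] = (1 - pc) * fj[i, a, j, b] + pc / (A20 * A20)
    return out


def oracle_conservation(f, q):
    C = np.zeros(f.shape[0])
    for i in range(f.shape[0]):
        s = 0.0
        for a in range(f.shape[1]):
            if f[i, a] > 0:
                s += f[i, a] * np.log(f[i, a] / q[a])
        C[i] = s
    return C


def oracle_weights(f, q):
    k = np.zeros_like(f)
    for i in range(f.shape[0]):
        for a in range(f.shape[1]):
            k[i, a] = np.log(f[i, a] * (1 - q[a]) / (q[a] * (1 - f[i, a])))
    return k


def oracle_coupling(fj, f, k):
    L = f.shape[0]
    C = np.zeros((L, L))
    for i in range(L):
        for j in range(L):
            s = 0.0
            for a in range(f.shape[1]):
                for b in range(f.shape[1]):
                    s += (k[i, a] * k[j, b]) ** 2 * (
                        fj[i, a, j, b] - f[i, a] * f[j, b]
                    ) ** 2
            C[i, j] = s
    return C


def oracle_pearson(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    return ((x - mx) * (y - my)).sum() / np.sqrt(
        ((x - mx) ** 2).sum() * ((y - my) ** 2).sum()
    )


# ---------------------------------------------------------------------------
# site frequencies
# ---------------------------------------------------------------------------

class TestSiteFrequencies:
    def test_simple_counting(self):
        aln = PeptideAlignment(["AAA", "AAA", "CCC"])
        fp = site_frequencies(aln, pseudocount=0.0)
        assert fp.f[0, 0] == pytest.approx(2 / 3)
        assert fp.f[0, 1] == pytest.approx(1 / 3)
        assert fp.f[0, 2:].sum() == 0

    def test_degenerate_column(self):
        aln = PeptideAlignment(["A", "A", "A"])
        fp = site_frequencies(aln, pseudocount=0.0)
        assert fp.f[0, 0] == 1.0
        assert fp.f[0, 1:].sum() == 0.0

    def test_matches_oracle(self, rng):
        aln = random_alignment(rng, 12, 4)
        fp = site_frequencies(aln, pseudocount=0.0)
        np.testing.assert_allclose(fp.f, oracle_site_freq(aln, 0.0), atol=1e-15)

    def test_matches_oracle_with_pseudocount(self, rng):
        aln = random_alignment(rng, 12, 4)
        fp = site_frequencies(aln, pseudocount=1e-3)
        np.testing.assert_allclose(fp.f, oracle_site_freq(aln, 1e-3), atol=1e-15)

    def test_rows_normalized_and_positive(self, rng):
        aln = random_alignment(rng, 7, 5)
        fp = site_frequencies(aln, pseudocount=1e-3)
        np.testing.assert_allclose(fp.f.sum(axis=1), 1.0, atol=1e-12)
        assert (fp.f > 0).all() and (fp.f < 1).all()

    def test_invalid_pseudocount(self, tiny_alignment):
        with pytest.raises(ValueError):
            site_frequencies(tiny_alignment, pseudocount=-0.1)


class TestBackground:
    def test_uniform(self, tiny_alignment):
        bg = background_frequencies(tiny_alignment, "uniform")
        np.testing.assert_allclose(bg.q, 0.05)

    def test_pooled_all_alanine(self):
        aln = PeptideAlignment(["AAA", "AAA"])
        bg = background_frequencies(aln, "pooled", pseudocount=1e-3)
        assert bg.q[0] == pytest.approx((1 - 1e-3) + 1e-3 / 20)

    def test_pooled_matches_global_tally(self, rng):
        aln = random_alignment(rng, 9, 6)
        bg = background_frequencies(aln, "pooled", pseudocount=1e-3)
        counts = np.zeros(A20)
        for seq in aln.sequences:
            for ch in seq:
                counts[ALPHABET.index(ch)] += 1
        expected = (1 - 1e-3) * counts / counts.sum() + 1e-3 / A20
        np.testing.assert_allclose(bg.q, expected, atol=1e-15)

    def test_unknown_mode(self, tiny_alignment):
        with pytest.raises(ValueError):
            background_frequencies(tiny_alignment, "shuffled")


class TestConservation:
    def test_zero_when_equal_to_background(self):
        f = np.full((3, A20), 1 / A20)
        fp = FrequencyProfile(f)
        bg = BackgroundFrequencies(np.full(A20, 1 / A20), "uniform")
        np.testing.assert_allclose(conservation(fp, bg).C, 0.0, atol=1e-14)

    def test_fixed_residue_equals_ln20(self):
        f = np.zeros((1, A20))
        f[0, 3] = 1.0
        fp = FrequencyProfile(f)
        bg = BackgroundFrequencies(np.full(A20, 1 / A20), "uniform")
        assert conservation(fp, bg).C[0] == pytest.approx(np.log(20), abs=1e-12)

    def test_matches_oracle(self, rng):
        aln = random_alignment(rng, 15, 4)
        fp = site_frequencies(aln, 1e-3)
        bg = background_frequencies(aln, "pooled", 1e-3)
        np.testing.assert_allclose(
            conservation(fp, bg).C, oracle_conservation(fp.f, bg.q), atol=1e-12
        )

    def test_non_negative(self, rng):
        for _ in range(10):
            aln = random_alignment(rng, 8, 5)
            fp = site_frequencies(aln, 1e-3)
            bg = background_frequencies(aln, "pooled", 1e-3)
            assert (conservation(fp, bg).C >= -1e-14).all()


class TestPositionalWeights:
    def test_zero_at_background(self):
        f = np.full((2, A20), 1 / A20)
        fp = FrequencyProfile(f)
        bg = BackgroundFrequencies(np.full(A20, 1 / A20), "uniform")
        np.testing.assert_allclose(positional_weights(fp, bg).k, 0.0, atol=1e-14)

    def test_ln19_closed_form(self):
        # f = 0.5 against q = 0.05: ln(0.5*0.95 / (0.05*0.5)) = ln 19
        f = np.full((1, A20), 0.5 / 19)
        f[0, 0] = 0.5
        fp = FrequencyProfile(f)
        bg = BackgroundFrequencies(np.full(A20, 0.05), "uniform")
        assert positional_weights(fp, bg).k[0, 0] == pytest.approx(np.log(19), abs=1e-12)

    def test_matches_oracle(self, rng):
        aln = random_alignment(rng, 11, 3)
        fp = site_frequencies(aln, 1e-3)
        bg = background_frequencies(aln, "pooled", 1e-3)
        np.testing.assert_allclose(
            positional_weights(fp, bg).k, oracle_weights(fp.f, bg.q), atol=1e-12
        )

    def test_domain_error_at_extreme_frequency(self):
        aln = PeptideAlignment(["AAA", "AAA"])
        fp = site_frequencies(aln, pseudocount=0.0)
        bg = BackgroundFrequencies(np.full(A20, 0.05), "uniform")
        with pytest.raises(ValueError, match="position 1"):
            positional_weights(fp, bg)


class TestJointFrequencies:
    def test_single_sequence(self):
        aln = PeptideAlignment(["AC"])
        jf = joint_frequencies(aln, pseudocount=0.0)
        assert jf.fj[0, 0, 1, 1] == 1.0
        assert jf.fj.sum(axis=(1, 3))[0, 1] == pytest.approx(1.0)

    def test_marginalization_identity(self, rng):
        aln = random_alignment(rng, 10, 4)
        for pc in (0.0, 1e-3):
            jf = joint_frequencies(aln, pc)
            fp = site_frequencies(aln, pc)
            expected = np.repeat(fp.f[:, :, None], aln.L, axis=2)
            np.testing.assert_allclose(jf.fj.sum(axis=3), expected, atol=1e-12)

    def test_symmetry(self, rng):
        aln = random_alignment(rng, 9, 4)
        jf = joint_frequencies(aln, 1e-3)
        np.testing.assert_allclose(jf.fj, jf.fj.transpose(2, 3, 0, 1), atol=0)

    def test_diagonal_blocks(self, rng):
        aln = random_alignment(rng, 8, 3)
        jf = joint_frequencies(aln, pseudocount=0.0)
        fp = site_frequencies(aln, pseudocount=0.0)
        for i in range(3):
            block = jf.fj[i, :, i, :]
            np.testing.assert_allclose(np.diag(block), fp.f[i], atol=1e-15)
            np.testing.assert_allclose(block - np.diag(np.diag(block)), 0.0)

    def test_matches_oracle(self, rng):
        aln = random_alignment(rng, 15, 4)
        for pc in (0.0, 1e-3):
            jf = joint_frequencies(aln, pc)
            np.testing.assert_allclose(jf.fj, oracle_joint_freq(aln, pc), atol=1e-15)

    def test_pairwise_normalization(self, rng):
        aln = random_alignment(rng, 6, 5)
        jf = joint_frequencies(aln, 1e-3)
        np.testing.assert_allclose(jf.fj.sum(axis=(1, 3)), 1.0, atol=1e-12)


class TestCouplingMatrix:
    def _stats(self, aln, pc=1e-3):
        fp = site_frequencies(aln, pc)
        bg = background_frequencies(aln, "pooled", pc)
        kw = positional_weights(fp, bg)
        jf = joint_frequencies(aln, pc)
        return fp, kw, jf

    def test_product_joint_gives_zero_offdiagonal(self, rng):
        aln = random_alignment(rng, 10, 4)
        fp, kw, jf = self._stats(aln)
        prod = np.einsum("ia,jb->iajb", fp.f, fp.f)
        cm = coupling_matrix(type(jf)(prod), fp, kw)
        off = cm.C2 - np.diag(np.diag(cm.C2))
        np.testing.assert_allclose(off, 0.0, atol=1e-12)

    def test_two_column_oracle(self):
        aln = PeptideAlignment(["AC"] * 5 + ["DE"] * 5)
        fp, kw, jf = self._stats(aln)
        cm = coupling_matrix(jf, fp, kw)
        np.testing.assert_allclose(
            cm.C2, oracle_coupling(jf.fj, fp.f, kw.k), atol=1e-12
        )

    def test_order_invariance(self, rng):
        aln = random_alignment(rng, 12, 4)
        shuffled = PeptideAlignment(
            [aln.sequences[i] for i in rng.permutation(aln.M)]
        )
        fp, kw, jf = self._stats(aln)
        fp2, kw2, jf2 = self._stats(shuffled)
        cm = coupling_matrix(jf, fp, kw)
        cm2 = coupling_matrix(jf2, fp2, kw2)
        np.testing.assert_allclose(cm.C2, cm2.C2, atol=1e-12)

    def test_symmetric_nonnegative(self, rng):
        aln = random_alignment(rng, 14, 5)
        fp, kw, jf = self._stats(aln)
        cm = coupling_matrix(jf, fp, kw)
        np.testing.assert_allclose(cm.C2, cm.C2.T, atol=1e-12)
        assert (cm.C2 >= -1e-14).all()


class TestCouplingPcc:
    def test_self_correlation(self, rng):
        m = rng.random((4, 4))
        m = m + m.T
        assert coupling_pcc(CouplingMatrix(m), CouplingMatrix(m)) == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        m = rng.random((4, 4))
        m = m + m.T
        n = 2.5 * m + 3.0
        assert coupling_pcc(CouplingMatrix(m), CouplingMatrix(n)) == pytest.approx(1.0)

    def test_fixed_matrices_match_textbook_formula(self):
        a = np.array([[1.0, 2.0, 0.5], [2.0, 3.0, 1.5], [0.5, 1.5, 2.0]])
        b = np.array([[0.4, 1.1, 0.3], [1.1, 2.9, 0.9], [0.3, 0.9, 1.7]])
        iu = np.triu_indices(3)
        expected = oracle_pearson(a[iu], b[iu])
        assert coupling_pcc(CouplingMatrix(a), CouplingMatrix(b)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_exclude_diagonal_flag(self):
        a = np.array([[10.0, 1.0, 2.0], [1.0, 20.0, 3.0], [2.0, 3.0, 30.0]])
        b = np.array([[10.0, 3.0, 2.0], [3.0, 20.0, 1.0], [2.0, 1.0, 30.0]])
        full = coupling_pcc(CouplingMatrix(a), CouplingMatrix(b), include_diagonal=True)
        off = coupling_pcc(CouplingMatrix(a), CouplingMatrix(b), include_diagonal=False)
        assert full > off  # diagonal agreement dominates

    def test_zero_variance_error(self):
        a = np.ones((3, 3))
        b = np.arange(9.0).reshape(3, 3)
        with pytest.raises(ValueError):
            coupling_pcc(CouplingMatrix(a), CouplingMatrix(b + b.T))

    def test_flat_pcc_against_oracle(self, rng):
        x, y = rng.random(30), rng.random(30)
        assert flat_pcc(x, y) == pytest.approx(oracle_pearson(x, y), abs=1e-12)


class TestIndependenceLimit:
    def test_independent_columns_have_weak_coupling(self):
        # columns sampled independently from one profile vs a coupled mixture
        # with the same marginals: off-diagonal coupling differs sharply
        from pepcore.synthdata import SyntheticSpec, exact_statistics, sample_msa

        rng = np.random.default_rng(7)
        L = 4
        base1 = rng.dirichlet(np.ones(A20), size=L) * 0.1
        base2 = rng.dirichlet(np.ones(A20), size=L) * 0.1
        p1, p2 = base1.copy(), base2.copy()
        for i in range(L):  # distinct dominant residues per component
            p1[i, 2 * i] += 0.9
            p2[i, 2 * i + 1] += 0.9
        mix = SyntheticSpec(np.array([0.5, 0.5]), np.stack([p1, p2]))
        f_mix, _ = exact_statistics(mix)
        indep = SyntheticSpec(np.array([1.0]), f_mix.f[None, :, :])

        def mean_offdiag(spec):
            aln = sample_msa(spec, 5000, seed=11)
            fp = site_frequencies(aln, 1e-3)
            bg = background_frequencies(aln, "pooled", 1e-3)
            kw = positional_weights(fp, bg)
            jf = joint_frequencies(aln, 1e-3)
            C = coupling_matrix(jf, fp, kw).C2
            return (C.sum() - np.trace(C)) / (L * (L - 1))

        assert mean_offdiag(indep) < 0.01 * mean_offdiag(mix)


class TestConservationPeaks:
    def test_anchor_positions_have_top_conservation(self, benchmark_suite):
        ds, registry = benchmark_suite
        for name, aln in ds.items():
            spec = registry[name]
            fp = site_frequencies(aln, 1e-3)
            bg = background_frequencies(aln, "pooled", 1e-3)
            C = conservation(fp, bg).C
            top = set(np.argsort(C)[-len(spec.anchor_positions):])
            assert top == set(spec.anchor_positions)
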