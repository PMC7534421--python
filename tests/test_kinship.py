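import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from opgp.data import GenotypeMatrix, PedigreeTable
from opgp.kinship import (RelationshipMatrix, blend_H, blend_HD, build_A,
                          build_D, build_G, fit_scaling, inbreeding,
                          min_eigenvalue, pedigree_dominance, read_matrix,
                          summarize_relationships, write_matrix)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def kinship_recursive(ped_dict, a, b, cache=None):
    """Wright's additive relationship by direct recursion (oracle)."""
    cache = {} if cache is None else cache
    key = (a, b) if a <= b else (b, a)
    if key in cache:
        return cache[key]
    order = {i: k for k, i in enumerate(ped_dict)}
    if order[a] < order[b]:
        a, b = b, a  # recurse through the younger individual
    dam, sire = ped_dict[a]
    if a == b:
        f = 0.5 * kinship_recursive(ped_dict, dam, sire, cache) \
            if dam and sire else 0.0
        val = 1.0 + f
    else:
        val = 0.0
        if dam:
            val += 0.5 * kinship_recursive(ped_dict, dam, b, cache)
        if sire:
            val += 0.5 * kinship_recursive(ped_dict, sire, b, cache)
    cache[key] = val
    return val


def vanraden_brute(codes, p):
    n, m = codes.shape
    denom = 2 * np.sum(p * (1 - p))
    G = np.zeros((n, n))
    for i in range(n):
        for k in range(n):
            s = 0.0
            for j in range(m):
                s += (codes[i, j] - 2 * p[j]) * (codes[k, j] - 2 * p[j])
            G[i, k] = s / denom
    return G


def dominance_brute(codes, p):
    n, m = codes.shape
    denom = 4 * np.sum((p * (1 - p)) ** 2)

    def wd(x, pj):
        return {0: -2 * pj**2, 1: 2 * pj * (1 - pj), 2: -2 * (1 - pj) ** 2}[int(x)]

    D = np.zeros((n, n))
    for i in range(n):
        for k in range(n):
            D[i, k] = sum(wd(codes[i, j], p[j]) * wd(codes[k, j], p[j])
                          for j in range(m)) / denom
    return D


def blend_oracle(A, ids, genotyped_idx, Gg, w):
    """Dense block-formula evaluation with explicit inverses (oracle)."""
    idx1 = [i for i in range(len(ids)) if i not in genotyped_idx]
    idx2 = list(genotyped_idx)
    A11 = A[np.ix_(idx1, idx1)]
    A12 = A[np.ix_(idx1, idx2)]
    A22 = A[np.ix_(idx2, idx2)]
    Gw = (1 - w) * Gg + w * A22
    A22i = np.linalg.inv(A22)
    H = np.zeros_like(A)
    H[np.ix_(idx1, idx1)] = (A11 - A12 @ A22i @ A12.T
                             + A12 @ A22i @ Gw @ A22i @ A12.T)
    H[np.ix_(idx1, idx2)] = A12 @ A22i @ Gw
    H[np.ix_(idx2, idx1)] = H[np.ix_(idx1, idx2)].T
    H[np.ix_(idx2, idx2)] = Gw
    order = idx1 + idx2
    return H[np.ix_(order, order)], [ids[i] for i in order]


def random_op_pedigree(seed, n_founders=6, n_prog=14):
    r = np.random.default_rng(seed)
    rows = [(f"F{i}", "", "", f"FAM{i}") for i in range(n_founders)]
    for k in range(n_prog):
        dam = int(r.integers(n_founders))
        sire = int(r.integers(n_founders))
        sire_id = f"F{sire}" if r.random() < 0.6 and sire != dam else ""
        rows.append((f"P{k}", f"F{dam}", sire_id, f"FAM{dam}"))
    return PedigreeTable(pd.DataFrame(
        rows, columns=["individual_id", "dam_id", "sire_id", "family_id"]))


# ---------------------------------------------------------------------------
# A matrix
# ---------------------------------------------------------------------------

class TestPedigreeA:
    def test_unrelated_founders_identity(self):
        ped = PedigreeTable(pd.DataFrame(
            [("A", "", "", "F1"), ("B", "", "", "F2")],
            columns=["individual_id", "dam_id", "sire_id", "family_id"]))
        np.testing.assert_array_equal(build_A(ped).values, np.eye(2))

    def test_half_sib_structure(self):
        ped = PedigreeTable(pd.DataFrame(
            [("M", "", "", "F1"), ("C1", "M", "", "F1"), ("C2", "M", "", "F1")],
            columns=["individual_id", "dam_id", "sire_id", "family_id"]))
        A = build_A(ped).to_dataframe()
        assert A.loc["M", "C1"] == 0.5      # mother-offspring, sire unknown
        assert A.loc["C1", "C2"] == 0.25    # maternal half sibs
        assert (np.diag(A) == 1.0).all()

    def test_inbred_offspring_diagonal(self):
        # dam mated to a relative: F = a(dam, sire)/2
        rows = [("G", "", "", "F1"), ("S0", "", "", "F2"),
                ("M", "G", "S0", "F1"), ("U", "G", "", "F1"),
                ("X", "M", "U", "F1")]  # parents M,U share grandmother G
        ped = PedigreeTable(pd.DataFrame(
            rows, columns=["individual_id", "dam_id", "sire_id", "family_id"]))
        A = build_A(ped).to_dataframe()
        a_parents = A.loc["M", "U"]
        assert A.loc["X", "X"] == pytest.approx(1 + a_parents / 2)
        assert inbreeding(build_A(ped))["X"] == pytest.approx(a_parents / 2)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_recursive_oracle(self, seed):
        ped = random_op_pedigree(seed)
        A = build_A(ped)
        ped_dict = {r.individual_id: (r.dam_id or None, r.sire_id or None)
                    for r in ped.table.itertuples()}
        cache = {}
        df = A.to_dataframe()
        for a in ped.ids[::3]:
            for b in ped.ids[::2]:
                assert df.loc[a, b] == pytest.approx(
                    kinship_recursive(ped_dict, a, b, cache), abs=1e-12)

    def test_founder_inbreeding_zero(self):
        ped = random_op_pedigree(9)
        F = inbreeding(build_A(ped))
        assert (F[ped.founder_ids] == 0).all()

    def test_positive_semidefinite(self):
        assert min_eigenvalue(build_A(random_op_pedigree(5))) > -1e-10


# ---------------------------------------------------------------------------
# G and D matrices
# ---------------------------------------------------------------------------

def _geno(codes):
    codes = np.asarray(codes, dtype=float)
    return GenotypeMatrix([f"i{k}" for k in range(codes.shape[0])],
                          [f"m{k}" for k in range(codes.shape[1])], codes)


class TestGenomicMatrices:
    def test_single_marker_self_relationships(self):
        # p = 0.5: heterozygote has zero additive but unit dominance self-rel.
        g = _geno([[1.0], [2.0], [0.0], [1.0]])
        G = build_G(g).values
        D = build_D(g).values
        assert G[0, 0] == pytest.approx(0.0)
        assert G[1, 1] == pytest.approx(2.0)
        assert D[0, 0] == pytest.approx(1.0)
        assert D[1, 1] == pytest.approx(1.0)
        assert D[2, 2] == pytest.approx(1.0)

    def test_brute_force_oracles_10x50(self, rng):
        codes = rng.binomial(2, rng.uniform(0.1, 0.9, size=50),
                             size=(10, 50)).astype(float)
        g = _geno(codes)
        p = g.allele_freq
        np.testing.assert_allclose(build_G(g).values,
                                   vanraden_brute(codes, p), atol=1e-10)
        np.testing.assert_allclose(build_D(g).values,
                                   dominance_brute(codes, p), atol=1e-10)

    def test_centering_property(self):
        r = np.random.default_rng(5)
        codes = r.binomial(2, r.uniform(0.15, 0.85, size=800),
                           size=(200, 800)).astype(float)
        g = _geno(codes)
        # additive coding is centered exactly by the sample frequencies
        assert np.abs(build_G(g).values.mean(axis=0)).max() < 1e-8
        # dominance coding is centered only in Hardy-Weinberg expectation
        assert abs(build_D(g).values.mean()) < 0.05

    def test_mean_diag_reflects_genomic_inbreeding(self):
        # Hardy-Weinberg, unrelated: mean diag(G) ~ 1
        r = np.random.default_rng(7)
        codes = r.binomial(2, r.uniform(0.2, 0.8, size=800),
                           size=(200, 800)).astype(float)
        G = build_G(_geno(codes))
        assert np.diag(G.values).mean() == pytest.approx(1.0, abs=0.05)

    def test_monomorphic_error(self):
        with pytest.raises(ValueError, match="monomorphic"):
            build_G(_geno(np.full((5, 3), 2.0)))
        with pytest.raises(ValueError, match="monomorphic"):
            build_D(_geno(np.full((5, 3), 2.0)))

    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_and_psd_property(self, seed):
        r = np.random.default_rng(seed)
        codes = r.binomial(2, r.uniform(0.1, 0.9, size=30),
                           size=(8, 30)).astype(float)
        for build in (build_G, build_D):
            try:
                M = build(_geno(codes))
            except ValueError:
                continue
            assert np.allclose(M.values, M.values.T)
            assert min_eigenvalue(M) > -1e-8


# ---------------------------------------------------------------------------
# scaling and single-step blending
# ---------------------------------------------------------------------------

class TestScaling:
    def test_moment_system_example(self):
        ids = list("abcd")
        G = RelationshipMatrix("G", ids, np.eye(4))  # avg diag 1, offdiag 0
        A22 = RelationshipMatrix("A", ids, 1.02 * np.eye(4)
                                 + 0.02 * (1 - np.eye(4)))
        sf, Ga = fit_scaling(G, A22)
        assert sf.beta == pytest.approx(1.0)
        assert sf.alpha == pytest.approx(0.02)

    def test_identity_when_already_matched(self, rng):
        codes = rng.binomial(2, rng.uniform(0.2, 0.8, 40), size=(6, 40)).astype(float)
        G = build_G(_geno(codes))
        sf, Ga = fit_scaling(G, RelationshipMatrix("A", G.ids, G.values.copy()))
        assert sf.beta == pytest.approx(1.0)
        assert sf.alpha == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(Ga.values, G.values, atol=1e-12)

    def test_moments_match_after_scaling(self, rng):
        codes = rng.binomial(2, rng.uniform(0.2, 0.8, 60), size=(9, 60)).astype(float)
        G = build_G(_geno(codes))
        a22 = np.eye(9) + 0.04
        A22 = RelationshipMatrix("A", G.ids, a22)
        _, Ga = fit_scaling(G, A22)
        n = 9
        assert np.trace(Ga.values) / n == pytest.approx(np.trace(a22) / n, abs=1e-12)
        off = lambda m: (m.sum() - np.trace(m)) / (n * (n - 1))
        assert off(Ga.values) == pytest.approx(off(a22), abs=1e-12)

    def test_degenerate_moments_error(self):
        ids = ["a", "b"]
        G = RelationshipMatrix("G", ids, np.ones((2, 2)))
        with pytest.raises(ValueError, match="singular"):
            fit_scaling(G, RelationshipMatrix("A", ids, np.eye(2)))


class TestSingleStepBlend:
    def _setup(self, seed=11):
        ped = random_op_pedigree(seed, n_founders=3, n_prog=7)
        A = build_A(ped)
        genotyped = list(A.ids[-4:])
        return ped, A, genotyped

    def test_blend_with_own_block_returns_A(self):
        _, A, genotyped = self._setup()
        A22 = A.submatrix(genotyped, kind="Ga")
        H = blend_H(A, A22, genotyped)
        np.testing.assert_allclose(H.submatrix(A.ids).values, A.values,
                                   atol=1e-10)

    def test_all_genotyped_returns_genomic_matrix(self, rng):
        codes = rng.binomial(2, rng.uniform(0.2, 0.8, 50), size=(5, 50)).astype(float)
        G = build_G(_geno(codes))
        A = RelationshipMatrix("A", G.ids, np.eye(5))
        H = blend_H(A, G, list(G.ids), w=0.0)
        np.testing.assert_allclose(H.values, G.values, atol=1e-12)

    @pytest.mark.parametrize("w", [0.0, 0.05])
    def test_matches_block_algebra_oracle(self, w, rng):
        _, A, genotyped = self._setup()
        codes = rng.binomial(2, rng.uniform(0.2, 0.8, 60), size=(4, 60)).astype(float)
        Gg = build_G(GenotypeMatrix(genotyped, [f"m{j}" for j in range(60)], codes))
        _, Ga = fit_scaling(Gg, A.submatrix(genotyped))
        H = blend_H(A, Ga, genotyped, w=w)
        gidx = [list(A.ids).index(i) for i in genotyped]
        expected, order = blend_oracle(A.values, list(A.ids), gidx, Ga.values, w)
        np.testing.assert_allclose(H.submatrix(order).values, expected, atol=1e-10)

    def test_genotyped_block_is_exactly_Ga_at_w0(self, rng):
        _, A, genotyped = self._setup()
        codes = rng.binomial(2, rng.uniform(0.2, 0.8, 60), size=(4, 60)).astype(float)
        Gg = build_G(GenotypeMatrix(genotyped, [f"m{j}" for j in range(60)], codes))
        _, Ga = fit_scaling(Gg, A.submatrix(genotyped))
        H = blend_H(A, Ga, genotyped, w=0.0)
        np.testing.assert_allclose(H.submatrix(genotyped).values, Ga.values,
                                   atol=1e-12)

    def test_hd_identity_pedigree_block_diagonal(self, rng):
        # pure half-sib pedigree dominance = I -> HD block diagonal with GD
        ped = random_op_pedigree(13, n_founders=3, n_prog=6)
        AD = pedigree_dominance(ped)
        genotyped = list(ped.ids[-3:])
        codes = rng.binomial(2, rng.uniform(0.2, 0.8, 40), size=(3, 40)).astype(float)
        GD = build_D(GenotypeMatrix(genotyped, [f"m{j}" for j in range(40)], codes))
        HD = blend_HD(AD, GD, genotyped, w=0.0)
        df = HD.to_dataframe()
        others = [i for i in ped.ids if i not in genotyped]
        np.testing.assert_allclose(df.loc[others, genotyped].to_numpy(), 0.0,
                                   atol=1e-12)
        np.testing.assert_allclose(df.loc[others, others].to_numpy(),
                                   np.eye(len(others)), atol=1e-12)
        np.testing.assert_allclose(df.loc[genotyped, genotyped].to_numpy(),
                                   GD.values, atol=1e-12)

    def test_hd_blend_with_own_block_returns_AD(self):
        ped, _, genotyped = self._setup()
        AD = pedigree_dominance(ped)
        GD = AD.submatrix(genotyped, kind="GD")
        HD = blend_HD(AD, GD, genotyped)
        np.testing.assert_allclose(HD.submatrix(AD.ids).values, AD.values,
                                   atol=1e-12)


class TestRelationshipSummary:
    def test_identity_has_no_high_pairs(self):
        M = RelationshipMatrix("G", list("abcd"), np.eye(4))
        s = summarize_relationships(M, threshold=0.1)
        assert s["frac_above"] == 0.0
        assert s["inbred_ids"] == []

    def test_enumerated_fractions(self):
        v = np.eye(4)
        v[0, 1] = v[1, 0] = 0.3
        v[2, 3] = v[3, 2] = 0.15
        M = RelationshipMatrix("G", list("abcd"), v)
        s = summarize_relationships(M, threshold=0.1)
        assert s["frac_above"] == pytest.approx(2 / 6)
        assert s["frac_below"] == pytest.approx(4 / 6)

    def test_inbred_flagging(self):
        v = np.eye(3)
        v[1, 1] = 1.3
        M = RelationshipMatrix("G", list("abc"), v)
        assert summarize_relationships(M)["inbred_ids"] == ["b"]


def test_matrix_round_trip(tmp_path, rng):
    codes = rng.binomial(2, rng.uniform(0.2, 0.8, 30), size=(6, 30)).astype(float)
    G = build_G(_geno(codes))
    path = tmp_path / "G.csv"
    write_matrix(G, path)
    again = read_matrix(path, "G")
    assert list(again.ids) == list(G.ids)
    np.testing.assert_allclose(again.values, G.values, atol=1e-12)
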