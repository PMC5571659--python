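import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import assocnet as an
from assocnet.genotypes import _r2_vectors

from conftest import make_matrix

VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=Chr01>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
Chr01\t100\t.\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1
Chr01\t200\t.\tC\tT,G\t.\t.\t.\tGT\t0/0\t0/1\t1/2
Chr01\t300\t.\tG\tA\t.\t.\t.\tGT\t./.\t0/0\t1/1
"""


class TestLoading:
    def test_vcf_dosage_coding_and_triallelic_skip(self, tmp_path):
        path = tmp_path / "toy.vcf"
        path.write_text(VCF_TEXT)
        with pytest.warns(UserWarning, match="skipped 1"):
            G = an.load_genotypes(path, format="vcf")
        assert G.accessions == ["s1", "s2", "s3"]
        # triallelic record absent
        assert [v.pos for v in G.variants] == [100, 300]
        np.testing.assert_array_equal(G.dosages[:, 0], [0, 1, 2])
        assert np.isnan(G.dosages[0, 1])
        np.testing.assert_array_equal(G.dosages[1:, 1], [0, 2])

    def test_tsv_round_trip(self, tmp_path, tiny_panel):
        G = tiny_panel.take_variants(np.arange(20))
        path = tmp_path / "geno.tsv"
        an.write_genotypes_tsv(G, path)
        G2 = an.load_genotypes(path, format="tsv")
        assert G2.accessions == G.accessions
        assert G2.ids == G.ids
        np.testing.assert_array_equal(G2.dosages, G.dosages)

    def test_invalid_dosage_rejected(self):
        with pytest.raises(an.GenotypeError, match="dosages"):
            make_matrix([[0, 3], [1, 2]])

    def test_unsorted_positions_rejected(self):
        v = [an.VariantRecord("Chr01", 200), an.VariantRecord("Chr01", 100)]
        with pytest.raises(an.GenotypeError, match="sorted"):
            an.GenotypeMatrix(["a", "b"], v, np.zeros((2, 2)))


class TestFilter:
    def test_low_maf_and_high_missing_dropped(self):
        # variant 0: alt freq 0.04 -> dropped; variant 1: MAF 0.5, kept;
        # variant 2: missing in 2/10 samples (rate 0.2) -> dropped
        n = 25
        col0 = np.zeros(n)
        col0[0] = 2  # p = 2/50 = 0.04
        col1 = np.tile([0, 2], 13)[:n]
        G = make_matrix(np.column_stack([col0, col1]))
        out = an.filter_variants(G, maf_min=0.05, miss_max=0.1)
        assert out.ids == [G.ids[1]]
        assert out.accessions == G.accessions

    def test_missing_rate_rule(self):
        col = np.tile([0.0, 2.0], 5)
        miss = col.copy()
        miss[:2] = np.nan  # rate 0.2
        G = make_matrix(np.column_stack([col, miss]))
        out = an.filter_variants(G, maf_min=0.05, miss_max=0.1)
        assert out.n_variants == 1

    def test_identity_and_idempotence(self, tiny_panel):
        out = an.filter_variants(tiny_panel)
        again = an.filter_variants(out)
        np.testing.assert_array_equal(out.dosages, again.dosages)
        # the generator enforces MAF >= 0.05 with no missingness
        assert out.n_variants == tiny_panel.n_variants


class TestImputation:
    def test_single_missing_cell_nearest_neighbour(self):
        # accession 0 lacks variant 0; accession 1 is its unique nearest
        # neighbour (distance 0 over co-observed variants) with dosage 2
        d = np.array(
            [
                [np.nan, 2, 0, 2, 0],
                [2, 2, 0, 2, 0],
                [0, 0, 2, 0, 2],
                [0, 0, 2, 2, 2],
            ]
        )
        out = an.impute_knn(make_matrix(d), k=1)
        assert out.dosages[0, 0] == 2.0
        assert not np.isnan(out.dosages).any()

    def test_no_missing_is_identity(self, tiny_panel):
        out = an.impute_knn(tiny_panel, k=3)
        np.testing.assert_array_equal(out.dosages, tiny_panel.dosages)

    def test_observed_cells_never_modified_and_concordance(self, tiny_panel):
        # a panel with close relatives: each accession has a near-duplicate,
        # the relatedness signal global kNN is designed to exploit
        rng = np.random.default_rng(4)
        half = tiny_panel.dosages[:100]
        twins = half.copy()
        flip = rng.random(twins.shape) < 0.02
        twins[flip] = 2.0 - twins[flip]
        d = np.vstack([half, twins])
        mask = rng.random(d.shape) < 0.05
        # keep at least one observed call per variant
        mask &= ~(np.cumsum(mask, axis=0) >= d.shape[0] - 1)
        masked = d.copy()
        masked[mask] = np.nan
        G = an.GenotypeMatrix(
            [f"a{i}" for i in range(d.shape[0])], tiny_panel.variants, masked
        )
        out = an.impute_knn(G, k=1)
        np.testing.assert_array_equal(out.dosages[~mask], d[~mask])
        acc = (out.dosages[mask] == d[mask]).mean()
        # all-major-allele baseline
        p = np.nanmean(masked, axis=0) / 2
        major = np.where(p > 0.5, 2.0, 0.0)
        base = (np.broadcast_to(major, d.shape)[mask] == d[mask]).mean()
        assert acc > base

    def test_all_missing_variant_raises(self):
        d = np.array([[np.nan, 0.0], [np.nan, 2.0], [np.nan, 2.0]])
        with pytest.raises(an.ImputationError, match="missing in all"):
            an.impute_knn(make_matrix(d), k=1)


class TestKinship:
    def test_identical_and_opposite_rows(self):
        d = np.array([[0, 0, 0], [0, 0, 0], [2, 2, 2]], dtype=float)
        K = an.kinship_simple_matching(make_matrix(d))
        assert K.values[0, 1] == pytest.approx(1.0)
        assert K.values[0, 2] == pytest.approx(0.0)

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(6)
        d = rng.integers(0, 3, size=(6, 20)).astype(float)
        K = an.kinship_simple_matching(make_matrix(d))
        for i in range(6):
            for j in range(6):
                expect = np.mean(1.0 - np.abs(d[i] - d[j]) / 2.0)
                assert K.values[i, j] == pytest.approx(expect, abs=1e-12)

    def test_psd_with_ridge_and_unit_diagonal(self, tiny_panel):
        K = an.kinship_simple_matching(tiny_panel)
        np.testing.assert_allclose(np.diag(K.values), 1.0)
        w = np.linalg.eigvalsh(K.values + 1e-6 * np.eye(K.values.shape[0]))
        assert w.min() > 0
        assert K.values.min() >= 0 and K.values.max() <= 1

    def test_missing_cells_rejected(self):
        d = np.array([[np.nan, 0.0], [0.0, 2.0]])
        with pytest.raises(an.GenotypeError, match="complete"):
            an.kinship_simple_matching(make_matrix(d))


class TestPCA:
    def test_identical_accessions_zero_scores(self):
        d = np.tile([0.0, 2.0, 1.0, 0.0], (5, 1))
        scores = an.genotype_pca(make_matrix(d), n_components=2)
        np.testing.assert_allclose(scores, 0.0, atol=1e-10)

    def test_scores_orthogonal(self, tiny_panel):
        scores = an.genotype_pca(tiny_panel, n_components=3)
        G = scores.T @ scores
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0.0, atol=1e-8)

    def test_two_cluster_separation(self):
        G = an.simulate_panel(
            an.PanelConfig(
                n_accessions=80, n_variants=400, n_chromosomes=2, n_subpops=2,
                fst_like_divergence=0.35, seed=5,
            )
        )
        pc1 = an.genotype_pca(G, n_components=1)[:, 0]
        half = G.n_accessions // 2
        signs_a, signs_b = np.sign(pc1[:half]), np.sign(pc1[half:])
        assert len(set(signs_a)) == 1 and len(set(signs_b)) == 1
        assert signs_a[0] != signs_b[0]

    def test_matches_svd_oracle_up_to_sign(self):
        rng = np.random.default_rng(11)
        d = rng.integers(0, 3, size=(10, 50)).astype(float)
        scores = an.genotype_pca(make_matrix(d), n_components=3)
        Xc = d - d.mean(axis=0)
        U, s, _ = np.linalg.svd(Xc, full_matrices=False)
        oracle = U[:, :3] * s[:3]
        for k in range(3):
            assert min(
                np.abs(scores[:, k] - oracle[:, k]).max(),
                np.abs(scores[:, k] + oracle[:, k]).max(),
            ) < 1e-8

    def test_rank_exceeded(self):
        d = np.array([[0.0, 2.0], [2.0, 0.0]])
        with pytest.raises(an.GenotypeError, match="rank"):
            an.genotype_pca(make_matrix(d), n_components=4)


class TestLd:
    def test_hand_computed_r2(self):
        d = np.column_stack([[0, 1, 2, 0, 2], [0, 2, 2, 0, 1]]).astype(float)
        G = make_matrix(d)
        r = np.corrcoef(d[:, 0], d[:, 1])[0, 1]
        val = an.ld_r2(G, G.ids[0], G.ids[1])
        assert val.r2 == pytest.approx(r * r, abs=1e-12)
        assert val.r2 == pytest.approx(0.5625, abs=1e-9)

    def test_duplicate_and_complement_columns(self):
        x = np.array([0, 1, 2, 0, 2.0])
        G = make_matrix(np.column_stack([x, x, 2 - x]))
        assert an.ld_r2(G, G.ids[0], G.ids[1]).r2 == pytest.approx(1.0)
        assert an.ld_r2(G, G.ids[0], G.ids[2]).r2 == pytest.approx(1.0)

    def test_monomorphic_raises(self):
        G = make_matrix(np.column_stack([[0, 0, 0, 0.0], [0, 1, 2, 0.0]]))
        with pytest.raises(an.LdUndefinedError):
            an.ld_r2(G, G.ids[0], G.ids[1])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.integers(0, 2), min_size=5, max_size=30), st.data())
    def test_symmetry_and_allele_relabel_invariance(self, xs, data):
        x = np.array(xs, dtype=float)
        ys = data.draw(
            st.lists(st.integers(0, 2), min_size=len(xs), max_size=len(xs))
        )
        y = np.array(ys, dtype=float)
        if x.std() == 0 or y.std() == 0:
            return
        assert _r2_vectors(x, y) == pytest.approx(_r2_vectors(y, x), abs=1e-12)
        assert _r2_vectors(2 - x, y) == pytest.approx(_r2_vectors(x, y), abs=1e-9)
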