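import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cgmtap.markers import (KinshipMatrix, MarkerMatrix, compute_kinship,
                            filter_markers, impute_missing, ld_prune,
                            read_csv_matrix, read_plink_raw, read_vcf)
from _oracles import naive_kinship


def _panel(g, positions=None, **kw):
    n, L = np.asarray(g).shape
    return MarkerMatrix(np.asarray(g, float), [f"V{i}" for i in range(n)],
                        [f"M{l}" for l in range(L)], positions, **kw)


class TestFilterMarkers:
    def test_balanced_marker_retained_and_monomorphic_removed(self):
        g = np.column_stack([
            np.tile([1.0, 0.0], 5),      # p = 0.5, clean -> keep
            np.ones(10),                  # monomorphic -> drop
        ])
        out = filter_markers(_panel(g))
        assert out.marker_ids == ["M0"]

    def test_matches_per_marker_recount(self, rng):
        n, L = 60, 100
        p = rng.uniform(0.0, 0.6, L)
        g = (rng.random((n, L)) < p).astype(float)
        g[rng.random((n, L)) < 0.03] = 0.5
        g[rng.random((n, L)) < 0.04] = np.nan
        out = filter_markers(_panel(g))
        expected = []
        for l in range(L):  # independent recount of the three rates
            col = g[:, l]
            obs = col[~np.isnan(col)]
            pl = obs.mean()
            maf = min(pl, 1 - pl)
            het = (obs == 0.5).mean()
            miss = np.isnan(col).mean()
            if maf >= 0.05 and het <= 0.05 and miss <= 0.05:
                expected.append(f"M{l}")
        assert out.marker_ids == expected
        assert 0 < len(expected) < L

    def test_all_removed_names_binding_criterion(self):
        with pytest.raises(ValueError, match="MAF"):
            filter_markers(_panel(np.ones((8, 3))))

    def test_filtered_freqs_within_band(self, rng):
        g = (rng.random((50, 80)) < rng.uniform(0, 1, 80)).astype(float)
        out = filter_markers(_panel(g))
        p = out.observed_freq()
        assert ((p >= 0.05) & (p <= 0.95)).all()


class TestLDPrune:
    def test_uncorrelated_all_retained(self, rng):
        g = (rng.random((40, 3)) < 0.5).astype(float)
        while np.any(np.abs(np.corrcoef(g.T) - np.eye(3)) > 0.85):
            g = (rng.random((40, 3)) < 0.5).astype(float)
        pos = np.column_stack([np.ones(3, int), np.arange(3) * 100])
        out = ld_prune(_panel(g, pos))
        assert out.n_markers == 3

    def test_identical_markers_keep_first(self, rng):
        col = (rng.random(30) < 0.5).astype(float)
        g = np.column_stack([col, col, col])
        pos = np.column_stack([np.ones(3, int), np.arange(3) * 10])
        out = ld_prune(_panel(g, pos))
        assert out.marker_ids == ["M0"]

    def test_perfect_ld_blocks_reduce_to_one_each(self, rng):
        blocks = [(rng.random(50) < 0.5).astype(float) for _ in range(10)]
        g = np.column_stack([b for b in blocks for _ in range(20)])
        pos = np.column_stack([np.ones(200, int), np.arange(200) * 7])
        out = ld_prune(_panel(g, pos))
        assert out.n_markers == 10
        # exhaustive postcondition: no retained pair within a window > r2
        codes = out.genotypes
        for a in range(out.n_markers):
            for b in range(a + 1, out.n_markers):
                r = np.corrcoef(codes[:, a], codes[:, b])[0, 1]
                assert r * r <= 0.8 + 1e-12

    def test_unsorted_positions_rejected(self, rng):
        g = (rng.random((20, 4)) < 0.5).astype(float)
        pos = np.column_stack([np.ones(4, int), [40, 10, 20, 30]])
        with pytest.raises(ValueError, match="sorted"):
            ld_prune(_panel(g, pos))


class TestImputeMissing:
    def test_single_missing_becomes_mean(self):
        g = np.array([[1.0], [0.0], [np.nan]])
        out = impute_missing(_panel(g))
        assert out.genotypes[2, 0] == pytest.approx(0.5)

    def test_no_missing_is_identity(self, rng):
        g = (rng.random((10, 5)) < 0.5).astype(float)
        out = impute_missing(_panel(g))
        np.testing.assert_array_equal(out.genotypes, g)

    def test_imputed_values_equal_column_means(self, rng):
        g = (rng.random((50, 20)) < rng.uniform(0.2, 0.8, 20)).astype(float)
        miss = rng.random((50, 20)) < 0.05
        g[miss] = np.nan
        out = impute_missing(_panel(g))
        for i, l in zip(*np.where(miss)):
            assert out.genotypes[i, l] == pytest.approx(np.nanmean(g[:, l]))
        assert not np.isnan(out.genotypes).any()

    def test_entirely_missing_marker_rejected(self):
        g = np.array([[1.0, np.nan], [0.0, np.nan]])
        with pytest.raises(ValueError, match="entirely missing"):
            impute_missing(_panel(g))

    def test_filter_then_impute_idempotent(self, rng):
        g = (rng.random((40, 30)) < rng.uniform(0.1, 0.9, 30)).astype(float)
        g[rng.random((40, 30)) < 0.03] = np.nan
        once = impute_missing(filter_markers(_panel(g)))
        twice = impute_missing(filter_markers(once))
        np.testing.assert_array_equal(once.genotypes, twice.genotypes)
        assert once.marker_ids == twice.marker_ids


class TestKinship:
    def test_two_variety_hand_example(self):
        m = MarkerMatrix(np.array([[1.0, 1.0], [0.0, 0.0]]), ["A", "B"], ["m1", "m2"],
                        allele_freq=np.array([0.5, 0.5]))
        K = compute_kinship(m)
        assert K.scale_b == pytest.approx(0.5)
        assert K.values[0, 0] == pytest.approx(1.0)
        assert K.values[0, 1] == pytest.approx(-1.0)

    def test_variety_at_frequency_has_zero_row(self, rng):
        g = (rng.random((10, 6)) < 0.5).astype(float)
        p = g.mean(axis=0)
        g2 = np.vstack([g, p])  # pseudo-variety sitting exactly at p
        m = MarkerMatrix(g2, [f"V{i}" for i in range(11)],
                         [f"M{l}" for l in range(6)], imputed=True,
                         allele_freq=p)
        K = compute_kinship(m)
        np.testing.assert_allclose(K.values[10], 0.0, atol=1e-12)

    def test_matches_naive_loop(self, rng):
        g = (rng.random((30, 500)) < rng.uniform(0.1, 0.9, 500)).astype(float)
        m = _panel(g)
        K = compute_kinship(m)
        K_ref, b_ref = naive_kinship(g, g.mean(axis=0))
        assert K.scale_b == pytest.approx(b_ref)
        assert np.abs(K.values - K_ref).max() < 1e-10

    def test_symmetric_psd(self, rng):
        g = (rng.random((25, 200)) < rng.uniform(0.1, 0.9, 200)).astype(float)
        K = compute_kinship(_panel(g))
        assert np.abs(K.values - K.values.T).max() < 1e-10
        ev = np.linalg.eigvalsh(K.values)
        assert ev.min() >= -1e-8 * ev.max()

    def test_monomorphic_panel_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            compute_kinship(_panel(np.ones((5, 4))))

    def test_missing_genotypes_rejected(self):
        g = np.array([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(ValueError, match="missing"):
            compute_kinship(_panel(g))

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_row_sums_reproduce_K_times_b(self, seed):
        rng = np.random.default_rng(seed)
        g = (rng.random((8, 12)) < rng.uniform(0.2, 0.8, 12)).astype(float)
        if np.all(g.std(axis=0) == 0):
            return
        m = _panel(g)
        K = compute_kinship(m)
        C = g - g.mean(axis=0)
        np.testing.assert_allclose(K.values * K.scale_b, C @ C.T, atol=1e-10)


class TestReaders:
    def test_vcf_reader(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
            "1\t100\tm1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
            "1\t200\tm2\tC\tT\t.\tPASS\t.\tGT\t./.\t0/0\t1/1\n")
        m = read_vcf(vcf)
        assert m.variety_ids == ["S1", "S2", "S3"]
        np.testing.assert_array_equal(m.genotypes[:, 0], [1.0, 0.5, 0.0])
        assert np.isnan(m.genotypes[0, 1])
        np.testing.assert_array_equal(m.positions[:, 1], [100, 200])

    def test_plink_raw_rescaled(self, tmp_path):
        raw = tmp_path / "t.raw"
        raw.write_text("FID IID PAT MAT SEX PHENOTYPE m1_A m2_C\n"
                       "F1 I1 0 0 1 -9 2 1\n"
                       "F2 I2 0 0 1 -9 0 2\n")
        m = read_plink_raw(raw)
        np.testing.assert_array_equal(m.genotypes, [[1.0, 0.5], [0.0, 1.0]])

    def test_csv_round_trip(self, tmp_path, rng):
        g = (rng.random((6, 4)) < 0.5).astype(float)
        m = _panel(g)
        m.to_csv(tmp_path / "g.csv")
        back = read_csv_matrix(tmp_path / "g.csv")
        np.testing.assert_array_equal(back.genotypes, g)
        assert back.variety_ids == m.variety_ids

    def test_kinship_csv_round_trip(self, tmp_path, rng):
        g = (rng.random((8, 50)) < 0.5).astype(float)
        K = compute_kinship(_panel(g))
        K.to_csv(tmp_path / "K.csv")
        back = KinshipMatrix.from_csv(tmp_path / "K.csv")
        np.testing.assert_allclose(back.values, K.values)
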