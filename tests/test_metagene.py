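import numpy as np
import pytest

from nucarray.core import GeneAnnotation, GenomeLayout
from nucarray.fragments import DyadTrack
from nucarray.metagene import (AlignedMatrix, align_matrix, composite,
                               heatmap_matrix, rescaled_metagene)


def ramp_track(layout):
    return DyadTrack({c: np.arange(l, dtype=float)
                      for c, l in layout.lengths.items()})


def const_track(layout, value=3.0):
    return DyadTrack({c: np.full(l, value) for c, l in layout.lengths.items()})


@pytest.fixture
def layout():
    return GenomeLayout(("chrA",), (10_000,))


@pytest.fixture
def plus_gene():
    return GeneAnnotation("gP", "chrA", "+", 2000, 4000, 2060)


@pytest.fixture
def minus_gene():
    return GeneAnnotation("gM", "chrA", "-", 8000, 6000, 7940)


class TestAlignMatrix:
    def test_plus_column_zero_is_anchor(self, layout, plus_gene):
        mat = align_matrix(ramp_track(layout), [plus_gene], 100, 200)
        assert mat.values[0, 100] == plus_gene.plus1_dyad  # column x = 0
        assert mat.values[0, 110] == plus_gene.plus1_dyad + 10

    def test_minus_strand_flips(self, layout, minus_gene):
        mat = align_matrix(ramp_track(layout), [minus_gene], 100, 200)
        # column +10 holds the value at plus1_dyad - 10
        assert mat.values[0, 110] == minus_gene.plus1_dyad - 10
        assert mat.values[0, 90] == minus_gene.plus1_dyad + 10

    def test_edge_masking(self, layout):
        g = GeneAnnotation("gE", "chrA", "+", 0, 2000, 5)
        mat = align_matrix(ramp_track(layout), [g], 100, 50)
        # columns -100..-6 fall before the chromosome: masked
        assert np.isnan(mat.values[0, :95]).all()
        assert np.isfinite(mat.values[0, 95:]).all()

    def test_unknown_chromosome(self, layout):
        g = GeneAnnotation("gX", "chrZ", "+", 0, 100, 10)
        with pytest.raises(ValueError, match="chrZ"):
            align_matrix(ramp_track(layout), [g], 10, 10)

    def test_strand_flip_mirrors_rows(self, layout, plus_gene):
        """Re-aligning the same anchor on the opposite strand gives the
        positionally mirrored row: M_flip[x] == M_orig[-x]."""
        flipped = GeneAnnotation("gP", "chrA", "-", 4000, 2000,
                                 plus_gene.plus1_dyad)
        track = ramp_track(layout)
        orig = align_matrix(track, [plus_gene], 300, 301)
        flip = align_matrix(track, [flipped], 300, 301)
        for x in range(-300, 301):
            assert flip.values[0, x + 300] == orig.values[0, -x + 300]


class TestComposite:
    def test_constant_matrix_is_one(self, layout, plus_gene, minus_gene):
        mat = align_matrix(const_track(layout, 7.5), [plus_gene, minus_gene],
                           100, 200)
        prof = composite(mat)
        np.testing.assert_allclose(prof.values, 1.0)

    def test_mean_before_normalization(self):
        mat = AlignedMatrix(["a", "b"], np.arange(-1, 2),
                            np.array([[0.0, 0.0, 0.0], [2.0, 2.0, 2.0]]))
        prof = composite(mat, norm_window=(-1, 2))
        np.testing.assert_allclose(prof.values, 1.0)  # mean 1, normed by 1

    def test_masked_column_excluded(self):
        vals = np.array([[1.0, np.nan], [3.0, np.nan]])
        mat = AlignedMatrix(["a", "b"], np.arange(0, 2), vals)
        prof = composite(mat, norm_window=(0, 2))
        assert np.isnan(prof.values[1])
        np.testing.assert_allclose(prof.values[0], 1.0)

    def test_norm_window_mean_is_one(self, mnase_track):
        track, genes = mnase_track
        mat = align_matrix(track, genes, 500, 1500)
        prof = composite(mat, norm_window=(0, 1000))
        sel = (prof.positions >= 0) & (prof.positions < 1000)
        assert abs(np.nanmean(prof.values[sel]) - 1.0) < 1e-9

    def test_zero_window_errors(self):
        mat = AlignedMatrix(["a"], np.arange(0, 3), np.zeros((1, 3)))
        with pytest.raises(ValueError, match="normalize"):
            composite(mat, norm_window=(0, 3))


class TestHeatmapMatrix:
    def make(self):
        return AlignedMatrix(["gene1", "gene2", "gene3"], np.arange(2),
                             np.array([[1., 1.], [2., 2.], [3., 3.]]))

    def test_sorts_by_key(self):
        out = heatmap_matrix(self.make(), {"gene1": 3, "gene2": 1, "gene3": 2})
        assert out.gene_ids == ["gene2", "gene3", "gene1"]
        np.testing.assert_array_equal(out.values[:, 0], [2, 3, 1])

    def test_ties_break_by_gene_id(self):
        out = heatmap_matrix(self.make(), {"gene1": 5, "gene2": 5, "gene3": 5})
        assert out.gene_ids == ["gene1", "gene2", "gene3"]

    def test_missing_key_errors(self):
        with pytest.raises(ValueError, match="gene3"):
            heatmap_matrix(self.make(), {"gene1": 1, "gene2": 2})

    def test_preserves_row_multiset(self):
        mat = self.make()
        out = heatmap_matrix(mat, {"gene1": 9, "gene2": 0, "gene3": 4})
        assert sorted(map(tuple, out.values.tolist())) == \
            sorted(map(tuple, mat.values.tolist()))


class TestRescaledMetagene:
    def test_double_length_body_bins_pairs(self, layout):
        g = GeneAnnotation("g", "chrA", "+", 2000, 4000, 2060)
        mat = rescaled_metagene(ramp_track(layout), [g], body_bins=1000,
                                flank=50)
        body = mat.values[0, 50:1050]
        expected = np.array([(2000 + 2 * i + 2000 + 2 * i + 1) / 2
                             for i in range(1000)])
        np.testing.assert_allclose(body, expected)

    def test_identity_when_body_equals_bins(self, layout):
        g = GeneAnnotation("g", "chrA", "+", 2000, 3000, 2060)
        mat = rescaled_metagene(ramp_track(layout), [g], body_bins=1000,
                                flank=10)
        np.testing.assert_allclose(mat.values[0, 10:1010],
                                   np.arange(2000, 3000))

    def test_short_body_interpolates(self, layout):
        g = GeneAnnotation("g", "chrA", "+", 2000, 2500, 2060)
        mat = rescaled_metagene(ramp_track(layout), [g], body_bins=1000,
                                flank=0)
        body = mat.values[0]
        assert len(body) == 1000
        assert np.all(np.diff(body) >= 0)          # ramp stays monotone
        np.testing.assert_allclose(body[0], 2000, atol=1.0)
        np.testing.assert_allclose(body[-1], 2499, atol=1.0)

    def test_constant_track_constant_output(self, layout):
        gp = GeneAnnotation("gp", "chrA", "+", 2000, 3700, 2060)
        gm = GeneAnnotation("gm", "chrA", "-", 9000, 5000, 8940)
        mat = rescaled_metagene(const_track(layout, 2.5), [gp, gm],
                                body_bins=500, flank=100)
        np.testing.assert_allclose(mat.values, 2.5)

    def test_minus_strand_reads_in_gene_direction(self, layout):
        g = GeneAnnotation("g", "chrA", "-", 4000, 2000, 3940)
        mat = rescaled_metagene(ramp_track(layout), [g], body_bins=2000,
                                flank=5)
        body = mat.values[0, 5:2005]
        np.testing.assert_allclose(body, np.arange(3999, 1999, -1))
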