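import math

import numpy as np
import pytest

from gagam import (
    Gene,
    GenomeAnnotation,
    GenomicInterval,
    PipelineConfig,
    RegulatoryRegion,
    build_gagam,
    build_gene_promoter_map,
    build_promoter_matrix,
    combine,
    exon_weight,
    label_peaks,
    normalize_gam,
    peaks_from_ids,
)

from conftest import make_pcm


class TestExonWeight:
    @pytest.mark.parametrize(
        "d, expected",
        [(0, 1.0), (5000, math.exp(-1)), (10000, math.exp(-2))],
    )
    def test_closed_forms(self, d, expected):
        assert exon_weight(d) == pytest.approx(expected, abs=1e-12)

    def test_monotone_decreasing(self):
        ds = np.linspace(0, 50_000, 60)
        ws = [exon_weight(d) for d in ds]
        assert all(a > b for a, b in zip(ws, ws[1:]))

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            exon_weight(-1)


class TestGenePromoterMap:
    def test_tss_disambiguates_shared_promoter_peak(self, worked):
        """A prom peak covering only one divergent gene's TSS is assigned to
        that gene even though it overlaps both promoter windows."""
        ds, exp = worked
        lps = label_peaks(ds.D.peaks(), ds.annotation)
        GP = build_gene_promoter_map(lps, ds.annotation.genes)
        assert GP.gene_ids == ["GENEA", "GENEB"]
        assert GP.matrix.toarray().tolist() == exp["GP"]

    def test_window_association_when_no_tss_covered(self, toy_annotation):
        # prom peak at [650,950) intersects G1's window [499,5000), covers no TSS
        lps = label_peaks(peaks_from_ids(["chr1:650-950"]), toy_annotation)
        GP = build_gene_promoter_map(lps, toy_annotation.genes)
        assert GP.gene_ids == ["G1"]
        assert GP.matrix.toarray().tolist() == [[1.0]]

    def test_golden_rule_excludes_promoterless_genes(self, toy_annotation):
        # only an exon peak: no prom association anywhere
        lps = label_peaks(peaks_from_ids(["chr1:1050-1150"]), toy_annotation)
        GP = build_gene_promoter_map(lps, toy_annotation.genes)
        assert GP.gene_ids == []

    def test_fuzz_deleting_promoter_evidence_removes_gene(self, toy_annotation):
        peaks = peaks_from_ids(["chr1:650-950", "chr1:1050-1150", "chr1:7900-8400"])
        lps = label_peaks(peaks, toy_annotation)
        assert build_gene_promoter_map(lps, toy_annotation.genes).gene_ids == ["G1"]
        # remove the promoter region: the same peaks no longer rescue G1
        stripped = GenomeAnnotation(
            toy_annotation.genes,
            [r for r in toy_annotation.regions if r.label != "promoter"],
            toy_annotation.chrom_order,
        )
        lps2 = label_peaks(peaks, stripped)
        assert build_gene_promoter_map(lps2, stripped.genes).gene_ids == []


class TestComponentMatrices:
    def test_promoter_matrix_hand_product(self, toy_annotation):
        lps = label_peaks(peaks_from_ids(["chr1:650-950"]), toy_annotation)
        GP = build_gene_promoter_map(lps, toy_annotation.genes)
        D = make_pcm([[0, 1, 0, 1]], peak_ids=["chr1:650-950"])
        assert build_promoter_matrix(GP, D).tolist() == [[0, 1, 0, 1]]

    def test_promoter_matrix_binarized_over_multiple_peaks(self):
        g = Gene("G", "G", GenomicInterval("chr1", 1000, 2000), "+",
                 (GenomicInterval("chr1", 1000, 2000),))
        regions = [
            RegulatoryRegion(GenomicInterval("chr1", 700, 800), "promoter"),
            RegulatoryRegion(GenomicInterval("chr1", 850, 950), "promoter"),
        ]
        ann = GenomeAnnotation([g], regions)
        peaks = ["chr1:650-840", "chr1:845-990"]
        lps = label_peaks(peaks_from_ids(peaks), ann)
        GP = build_gene_promoter_map(lps, ann.genes)
        D = make_pcm([[1, 0], [1, 0]], peak_ids=peaks)
        P = build_promoter_matrix(GP, D)
        assert P.tolist() == [[1.0, 0.0]]  # binary, not 2
        raw = build_promoter_matrix(GP, D, binarize=False)
        assert raw.tolist() == [[2.0, 0.0]]

    def test_worked_example_components(self, worked):
        ds, exp = worked
        gam, _ = build_gagam(
            ds.D, ds.annotation, ds.truth_connections, PipelineConfig(normalization="none")
        )
        np.testing.assert_allclose(gam.components["P"], exp["P"], atol=1e-12)
        np.testing.assert_allclose(gam.components["C"], exp["C"], atol=1e-12)
        np.testing.assert_allclose(gam.components["E"], exp["E"], atol=1e-12)

    def test_all_zero_matrix_gives_zero_components(self, worked):
        ds, _ = worked
        D0 = make_pcm(
            np.zeros((7, 3), dtype=int), peak_ids=ds.D.peak_ids, cell_ids=ds.D.cell_ids
        )
        gam, _ = build_gagam(
            D0, ds.annotation, ds.truth_connections, PipelineConfig(normalization="none")
        )
        for name in ("P", "C", "E"):
            assert not gam.components[name].any()

    def test_no_promoter_peak_anywhere_fails_golden_rule(self, toy_annotation):
        D = make_pcm([[1, 1]], peak_ids=["chr1:1050-1150"])  # exon peak only
        with pytest.raises(ValueError, match="golden rule"):
            build_gagam(D, toy_annotation)


class TestCombine:
    def test_single_component_identity(self, worked):
        ds, exp = worked
        cfg = PipelineConfig(weights=(1, 0, 0), normalization="none")
        gam, _ = build_gagam(ds.D, ds.annotation, ds.truth_connections, cfg)
        np.testing.assert_allclose(gam.gagam, gam.components["P"], atol=1e-15)

    def test_weight_linearity(self, worked):
        ds, _ = worked
        g1, _ = build_gagam(
            ds.D, ds.annotation, ds.truth_connections,
            PipelineConfig(weights=(1, 1, 1), normalization="none"),
        )
        g2, _ = build_gagam(
            ds.D, ds.annotation, ds.truth_connections,
            PipelineConfig(weights=(1, 1, 0), normalization="none"),
        )
        np.testing.assert_allclose(g1.gagam - g2.gagam, g1.components["E"], atol=1e-15)

    def test_nonbinary_weights_rejected(self):
        Z = np.zeros((1, 1))
        with pytest.raises(ValueError):
            combine(Z, Z, Z, ["g"], ["c"], weights=(2, 0, 0))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            combine(np.zeros((1, 2)), np.zeros((2, 2)), np.zeros((1, 2)), ["g"], ["c", "d"])

    @pytest.mark.parametrize("seed", range(4))
    def test_monotone_in_accessibility(self, worked, seed):
        """Opening one more peak never decreases any P/C/E entry."""
        ds, _ = worked
        rng = np.random.default_rng(seed)
        base = ds.D.matrix.toarray()
        zeros = np.argwhere(base == 0)
        r, c = zeros[rng.integers(len(zeros))]
        more = base.copy()
        more[r, c] = 1
        cfg = PipelineConfig(normalization="none")
        g0, _ = build_gagam(ds.D, ds.annotation, ds.truth_connections, cfg)
        D1 = make_pcm(more, peak_ids=ds.D.peak_ids, cell_ids=ds.D.cell_ids)
        g1, _ = build_gagam(D1, ds.annotation, ds.truth_connections, cfg)
        for name in ("P", "C", "E"):
            assert (g1.components[name] >= g0.components[name] - 1e-15).all()


class TestNormalization:
    def test_cell_total_rescales_to_median(self, worked):
        ds, _ = worked
        gam, _ = build_gagam(
            ds.D, ds.annotation, ds.truth_connections, PipelineConfig(normalization="none")
        )
        raw_sums = gam.gagam.sum(axis=0)
        norm = normalize_gam(gam, "cell_total")
        sums = norm.gagam.sum(axis=0)
        np.testing.assert_allclose(sums, np.median(raw_sums), atol=1e-9)

    def test_hand_example_column_sums(self):
        from gagam import GeneActivityMatrix

        gam = GeneActivityMatrix(np.array([[2.0, 4.0]]), ["g"], ["c0", "c1"])
        out = normalize_gam(gam, "cell_total")
        np.testing.assert_allclose(out.gagam, [[3.0, 3.0]])

    def test_zero_column_stays_zero(self):
        from gagam import GeneActivityMatrix

        gam = GeneActivityMatrix(np.array([[2.0, 0.0]]), ["g"], ["c0", "c1"])
        out = normalize_gam(gam, "cell_total")
        assert out.gagam[0, 1] == 0.0

    def test_none_is_identity(self):
        from gagam import GeneActivityMatrix

        X = np.array([[1.0, 2.0], [0.5, 0.0]])
        gam = GeneActivityMatrix(X.copy(), ["g1", "g2"], ["c0", "c1"])
        out = normalize_gam(gam, "none")
        np.testing.assert_array_equal(out.gagam, X)
        assert out.normalized


class TestMatrixIO:
    def test_mtx_round_trip(self, worked, tmp_path):
        ds, _ = worked
        ds.D.write(tmp_path / "m.mtx", tmp_path / "p.bed", tmp_path / "b.tsv")
        from gagam import PeakCellMatrix

        back = PeakCellMatrix.read(tmp_path / "m.mtx", tmp_path / "p.bed", tmp_path / "b.tsv")
        assert back.peak_ids == ds.D.peak_ids
        assert back.cell_ids == ds.D.cell_ids
        assert (back.matrix != ds.D.matrix).nnz == 0

    def test_nonbinary_matrix_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            make_pcm([[2, 0]])
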