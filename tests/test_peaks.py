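"""Peak/gene-model I/O and peak-location classification."""

import pytest

from loopblock import (
    FormatError,
    GeneModel,
    GenomicInterval,
    Peak,
    classify_peak_location,
    peaks_to_genes,
    read_gene_models,
    read_peaks,
)
from loopblock.peaks import CATEGORIES, write_peaks


def make_peak(chrom, start, end, name="p", summit=None, height=None):
    return Peak(
        interval=GenomicInterval(chrom, start, end, name=name),
        summit_offset=summit,
        summit_height=height,
    )


def plus_gene(gene_id="g", tss=10_000, tes=20_000, **kw):
    return GeneModel(
        gene_id=gene_id, chrom="chr1", strand="+", tss=tss, tes=tes,
        exons=((tss, tes),), **kw,
    )


class TestPeakIO:
    def test_narrowpeak_fields(self, tmp_path):
        path = tmp_path / "x.narrowPeak"
        path.write_text("chr1\t100\t200\tp1\t0\t.\t5.0\t-1\t-1\t50\n")
        (peak,) = read_peaks(path, "narrowpeak")
        assert peak.summit_offset == 50
        assert peak.summit_height == 5.0
        assert peak.anchor == 150

    def test_narrowpeak_minus_one_summit_is_absent(self, tmp_path):
        path = tmp_path / "x.narrowPeak"
        path.write_text("chr1\t100\t200\tp1\t0\t.\t5.0\t-1\t-1\t-1\n")
        (peak,) = read_peaks(path, "narrowpeak")
        assert peak.summit_offset is None
        assert peak.anchor == 150  # falls back to midpoint

    def test_bed6_has_no_summit(self, tmp_path):
        path = tmp_path / "x.bed"
        path.write_text("chr1\t100\t200\tp1\t7\t+\n")
        (peak,) = read_peaks(path, "bed6")
        assert peak.summit_offset is None and peak.summit_height is None
        assert peak.interval.score == 7

    def test_round_trip_preserves_fields(self, tmp_path):
        peaks = [
            make_peak("chr1", 0, 100, "a", summit=10, height=3.5),
            make_peak("chr2", 50, 80, "b"),
        ]
        path = tmp_path / "rt.narrowPeak"
        write_peaks(peaks, path, "narrowpeak")
        back = read_peaks(path, "narrowpeak")
        assert [(p.name, p.summit_offset) for p in back] == [("a", 10), ("b", None)]
        assert back[0].summit_height == 3.5

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "x.narrowPeak"
        path.write_text(
            "chr1\t100\t200\tp1\t0\t.\t5.0\t-1\t-1\t50\n"
            "chr1\t900\t200\tbad\t0\t.\t1.0\t-1\t-1\t-1\n"
        )
        with pytest.raises(FormatError, match="line 2"):
            read_peaks(path, "narrowpeak")


GTF = """\
chr1\tsrc\tgene\t1001\t2000\t.\t+\t.\tgene_id "gA";
chr1\tsrc\ttranscript\t1001\t2000\t.\t+\t.\tgene_id "gA"; transcript_id "gA.1";
chr1\tsrc\texon\t1001\t2000\t.\t+\t.\tgene_id "gA"; transcript_id "gA.1";
chr1\tsrc\tgene\t5001\t6000\t.\t-\t.\tgene_id "gB";
chr1\tsrc\ttranscript\t5001\t6000\t.\t-\t.\tgene_id "gB"; transcript_id "gB.1";
chr1\tsrc\texon\t5001\t6000\t.\t-\t.\tgene_id "gB"; transcript_id "gB.1";
chr1\tsrc\tgene\t9001\t12000\t.\t+\t.\tgene_id "gC";
chr1\tsrc\ttranscript\t9201\t12000\t.\t+\t.\tgene_id "gC"; transcript_id "gC.1";
chr1\tsrc\texon\t9201\t12000\t.\t+\t.\tgene_id "gC"; transcript_id "gC.1";
chr1\tsrc\ttranscript\t9001\t11000\t.\t+\t.\tgene_id "gC"; transcript_id "gC.2";
chr1\tsrc\texon\t9001\t11000\t.\t+\t.\tgene_id "gC"; transcript_id "gC.2";
"""


class TestGeneModels:
    @pytest.fixture()
    def genes(self, tmp_path):
        path = tmp_path / "genes.gtf"
        path.write_text(GTF)
        return {g.gene_id: g for g in read_gene_models(path, "gtf")}

    def test_plus_strand_coordinates(self, genes):
        assert (genes["gA"].tss, genes["gA"].tes) == (1000, 2000)

    def test_minus_strand_flips_tss(self, genes):
        assert (genes["gB"].tss, genes["gB"].tes) == (6000, 5000)

    def test_multi_transcript_uses_most_upstream_tss(self, genes):
        assert genes["gC"].tss == 9000
        assert genes["gC"].exons == ((9000, 12000),)  # union of the transcripts


class TestClassification:
    def test_promoter_window(self):
        gene = plus_gene()
        call = classify_peak_location(make_peak("chr1", 9400, 9600), [gene])
        assert call.category == "promoter" and call.gene_id == "g"

    def test_distal_enhancer_upstream_band(self):
        call = classify_peak_location(make_peak("chr1", 8200, 8400), [plus_gene()])
        assert call.category == "distal_enhancer"  # anchor at TSS-1700

    def test_minus_strand_promoter_is_mirrored(self):
        gene = GeneModel(
            gene_id="m", chrom="chr1", strand="-", tss=20_000, tes=10_000,
            exons=((10_000, 20_000),),
        )
        # 500 bp upstream of a minus-strand TSS is to the right of it
        call = classify_peak_location(make_peak("chr1", 20_450, 20_550), [gene])
        assert call.category == "promoter"

    def test_five_utr_counts_as_promoter(self):
        gene = plus_gene(five_utr=((12_000, 12_500),))
        call = classify_peak_location(make_peak("chr1", 12_200, 12_300), [gene])
        assert call.category == "promoter"

    def test_downstream_and_intron_and_exon(self):
        gene = GeneModel(
            gene_id="g", chrom="chr1", strand="+", tss=10_000, tes=20_000,
            exons=((10_000, 12_000), (15_000, 20_000)),
        )
        assert classify_peak_location(make_peak("chr1", 20_300, 20_500), [gene]).category == "distal_enhancer"
        assert classify_peak_location(make_peak("chr1", 13_000, 13_100), [gene]).category == "intron"
        assert classify_peak_location(make_peak("chr1", 11_000, 11_100), [gene]).category == "other"

    def test_far_peak_is_intergenic_with_nearest_gene(self):
        call = classify_peak_location(make_peak("chr1", 150_000, 150_200), [plus_gene()])
        assert call.category == "intergenic" and call.gene_id == "g"

    def test_empty_gene_set_gives_intergenic_none(self):
        call = classify_peak_location(make_peak("chr1", 100, 200), [])
        assert call.category == "intergenic" and call.gene_id is None

    def test_every_peak_gets_exactly_one_category(self, rng):
        genes = [plus_gene("g1", 10_000, 20_000), plus_gene("g2", 50_000, 55_000)]
        peaks = [
            make_peak("chr1", int(s), int(s) + 100)
            for s in rng.integers(0, 70_000, size=100)
        ]
        calls = [classify_peak_location(p, genes) for p in peaks]
        assert all(c.category in CATEGORIES for c in calls)
        counts = {cat: sum(c.category == cat for c in calls) for cat in CATEGORIES}
        assert sum(counts.values()) == len(peaks)

    def test_invariant_to_gene_order(self, rng):
        genes = [
            plus_gene("g1", 10_000, 20_000),
            plus_gene("g2", 19_500, 30_000),
            plus_gene("g3", 5_000, 9_500),
        ]
        peaks = [
            make_peak("chr1", int(s), int(s) + 50)
            for s in rng.integers(0, 35_000, size=200)
        ]
        fwd = [classify_peak_location(p, genes) for p in peaks]
        rev = [classify_peak_location(p, genes[::-1]) for p in peaks]
        assert [(c.category, c.gene_id) for c in fwd] == [
            (c.category, c.gene_id) for c in rev
        ]


class TestPeaksToGenes:
    def test_nearest_tss_wins(self):
        genes = [plus_gene("near", 10_500, 12_000), plus_gene("far", 15_000, 16_000)]
        peak = make_peak("chr1", 9_950, 10_050)
        assert peaks_to_genes([peak], genes)[peak] == frozenset({"near"})

    def test_equidistant_tss_reports_both(self):
        genes = [plus_gene("a", 9_000, 9_500), plus_gene("b", 11_000, 11_500)]
        peak = make_peak("chr1", 9_950, 10_050)
        assert peaks_to_genes([peak], genes)[peak] == frozenset({"a", "b"})

    def test_nothing_within_max_distance(self):
        peak = make_peak("chr1", 0, 100)
        assert peaks_to_genes([peak], [plus_gene(tss=500_000, tes=501_000)])[peak] == frozenset()
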