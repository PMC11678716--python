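"""Classify peaks relative to gene anatomy.

Peak anchors (summit, else midpoint) are assigned to one of five
mutually exclusive categories: promoter (-1000..+10 bp of the TSS or
5' UTR), distal enhancer (-2000..-1000 bp, 3' UTR, or <=1 kb downstream
of the TES), exonic ("other"), intronic, or intergenic.
"""

from loopblock import GeneModel, GenomicInterval, Peak, classify_peak_location

gene = GeneModel(
    gene_id="twist_like", chrom="chr2", strand="+", tss=100_000, tes=110_000,
    exons=((100_000, 102_000), (106_000, 110_000)),
)

peaks = {
    "at the promoter": Peak(GenomicInterval("chr2", 99_300, 99_700, name="p1")),
    "upstream enhancer band": Peak(GenomicInterval("chr2", 98_100, 98_500, name="p2")),
    "inside an intron": Peak(GenomicInterval("chr2", 103_500, 103_900, name="p3")),
    "far away": Peak(GenomicInterval("chr2", 400_000, 400_400, name="p4")),
}

for label, peak in peaks.items():
    call = classify_peak_location(peak, [gene])
    print(f"{label:>24}: {call.category:>15} (gene: {call.gene_id})")
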