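"""Classify pseudo-bulk ATAC regions into noDA / loss / gain.

Each region has one aggregate accessibility signal per condition
(wild type vs mutant); the class is decided by log2 fold change with a
pseudocount at threshold 1 (a two-fold change).
"""

from loopblock import AtacRegion, GenomicInterval, classify_atac

regions = [
    AtacRegion(GenomicInterval("chr1", 0, 500, name="stable"), wt_signal=120, mut_signal=110),
    AtacRegion(GenomicInterval("chr1", 1000, 1500, name="closing"), wt_signal=160, mut_signal=30),
    AtacRegion(GenomicInterval("chr1", 2000, 2500, name="opening"), wt_signal=40, mut_signal=170),
]

for r in classify_atac(regions, lfc_threshold=1.0, pseudocount=1.0):
    print(
        f"{r.interval.name:>8}: wt={r.wt_signal:>5.0f} mut={r.mut_signal:>5.0f} "
        f"-> {r.klass}"
    )
print("noDA = unchanged accessibility; loss/gain = at least two-fold change.")
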