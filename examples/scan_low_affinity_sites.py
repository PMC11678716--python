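"""Scan a region for low-affinity binding sites with a PSAM.

Builds a small position-specific affinity model from a consensus (every
mismatch costs a factor 0.3), plants one perfect site and one degraded
site in a random background, and prints the top-scoring windows.  A
score of 1.0 is the consensus; scores well below 1 are the low-affinity
sites that distance-stratified regions are enriched for.
"""

import numpy as np

from loopblock import AffinityModel, scan_region

consensus = "TTAATTAC"
penalty = 0.3
weights = np.full((len(consensus), 4), penalty)
for i, base in enumerate(consensus):
    weights[i, "ACGT".index(base)] = 1.0
model = AffinityModel.from_weights(weights, name="hox_like")

rng = np.random.default_rng(0)
seq = "".join(rng.choice(list("ACGT"), size=300))
degraded = "TTGATTAC"  # one mismatch -> relative affinity 0.3
seq = seq[:50] + consensus + seq[58:120] + degraded + seq[128:]

profile = scan_region("example_region", seq, model, k=5)
print(f"top {len(profile.top_windows)} windows (offset, strand, relative affinity):")
for w in profile.top_windows:
    print(f"  {w.offset:>4}  {w.strand}  {w.score:.4f}")
print(f"region summary score (mean of top-k): {profile.summary_score:.4f}")
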