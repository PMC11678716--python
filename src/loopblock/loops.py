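"""Associate TF peaks with a bait/target contact catalogue and assemble
distance-stratified chromatin-loop candidates.

The model: an anchor TF (a Hox-like factor) binds a subset of the
capture viewpoints ("baits", promoter-proximal regions) while a partner
TF (a Mef2-like factor) binds a subset of the distal interacting regions
("targets").  A loop candidate is a bound bait paired with a bound
target within a distance stratum — the configuration in which the
partner factor could hold a loop that blocks anchor-factor binding.
"""

from __future__ import annotations

import json
from collections.abc import Sequence
from dataclasses import dataclass

import pandas as pd

from .errors import ConfigurationError
from .intervals import (
    GenomicInterval,
    IntervalSet,
    intersect,
    stratify_by_distance,
)
from .peaks import Peak, peaks_to_genes

__all__ = [
    "LoopCandidate",
    "OverlapSummary",
    "associate_anchor_peaks",
    "associate_target_peaks",
    "build_loop_candidates",
    "peak_and_gene_overlap",
    "write_candidates",
    "write_loop_summary",
]


@dataclass(frozen=True)
class LoopCandidate:
    """A (bound bait, bound target) pair in a distance stratum, expanded
    with the specific peaks that bind each side."""

    bait_peak: Peak
    target_peak: Peak
    bait: GenomicInterval
    target: GenomicInterval
    gap: int
    stratum: int


@dataclass(frozen=True)
class OverlapSummary:
    """Two-way Venn counts.  At the peak level, ``n_common`` counts
    first-set peaks overlapping at least one second-set peak; at the gene
    level it is a plain set intersection."""

    n_a_only: int
    n_b_only: int
    n_common: int
    common_items: tuple[str, ...]


def _associate(
    tf_peaks: Sequence[Peak], regions: IntervalSet, what: str
) -> tuple[IntervalSet, float]:
    if len(regions) == 0:
        raise ConfigurationError(f"empty {what} set")
    peak_set = IntervalSet(p.interval for p in tf_peaks)
    bound = {a for a, _ in intersect(regions, peak_set, min_overlap=1)}
    return IntervalSet(bound), len(bound) / len(regions)


def associate_anchor_peaks(
    tf_peaks: Sequence[Peak], baits: IntervalSet
) -> tuple[IntervalSet, float]:
    """Baits with >= 1 base of anchor-TF peak overlap, and the bound fraction.
    A bait counts once however many peaks cover it."""
    return _associate(tf_peaks, baits, "bait")


def associate_target_peaks(
    tf_peaks: Sequence[Peak], targets: IntervalSet
) -> tuple[IntervalSet, float]:
    """Targets with >= 1 base of partner-TF peak overlap, and the bound fraction."""
    return _associate(tf_peaks, targets, "target")


def build_loop_candidates(
    bound_baits: IntervalSet,
    bound_targets: IntervalSet,
    anchor_peaks: Sequence[Peak],
    partner_peaks: Sequence[Peak],
    bounds: Sequence[int],
) -> list[LoopCandidate]:
    """Stratify bound baits against bound targets and expand each pair with
    its overlapping peaks (cartesian when several peaks cover one region)."""
    stratified = stratify_by_distance(bound_baits, bound_targets, bounds)
    anchor_by_iv = _peaks_by_region(bound_baits, anchor_peaks)
    partner_by_iv = _peaks_by_region(bound_targets, partner_peaks)
    candidates: list[LoopCandidate] = []
    for bound in stratified.bounds:
        for bait, target, g in stratified.strata.get(bound, []):
            for ap in anchor_by_iv.get(bait, []):
                for pp in partner_by_iv.get(target, []):
                    candidates.append(
                        LoopCandidate(
                            bait_peak=ap,
                            target_peak=pp,
                            bait=bait,
                            target=target,
                            gap=g,
                            stratum=bound,
                        )
                    )
    return candidates


def _peaks_by_region(
    regions: IntervalSet, peaks: Sequence[Peak]
) -> dict[GenomicInterval, list[Peak]]:
    by_iv: dict[GenomicInterval, list[Peak]] = {}
    peak_lookup: dict[GenomicInterval, list[Peak]] = {}
    for p in peaks:
        peak_lookup.setdefault(p.interval, []).append(p)
    peak_set = IntervalSet(peak_lookup)
    for region, piv in intersect(regions, peak_set, min_overlap=1):
        by_iv.setdefault(region, []).extend(peak_lookup[piv])
    return by_iv


def peak_and_gene_overlap(
    a_peaks: Sequence[Peak],
    b_peaks: Sequence[Peak],
    genes,
    max_distance: int = 50_000,
) -> tuple[OverlapSummary, OverlapSummary]:
    """Peak-level and gene-level two-way overlap summaries.

    Peak level uses 1-base interval intersection; gene level associates
    each peak set with nearest-TSS genes and intersects the gene sets.
    """
    a_set = IntervalSet(p.interval for p in a_peaks)
    b_set = IntervalSet(p.interval for p in b_peaks)
    pairs = intersect(a_set, b_set, min_overlap=1)
    a_hit = {a for a, _ in pairs}
    b_hit = {b for _, b in pairs}
    peak_level = OverlapSummary(
        n_a_only=len(a_set) - len(a_hit),
        n_b_only=len(b_set) - len(b_hit),
        n_common=len(a_hit),
        common_items=tuple(sorted(iv.name for iv in a_hit)),
    )
    genes_a = set().union(
        *peaks_to_genes(a_peaks, genes, max_distance).values(), set()
    )
    genes_b = set().union(
        *peaks_to_genes(b_peaks, genes, max_distance).values(), set()
    )
    gene_level = OverlapSummary(
        n_a_only=len(genes_a - genes_b),
        n_b_only=len(genes_b - genes_a),
        n_common=len(genes_a & genes_b),
        common_items=tuple(sorted(genes_a & genes_b)),
    )
    return peak_level, gene_level


# ---------------------------------------------------------------------------
# I/O

def write_candidates(candidates: Sequence[LoopCandidate], path) -> None:
    rows = [
        (
            c.bait.chrom, c.bait.start, c.bait.end, c.bait.name,
            c.target.chrom, c.target.start, c.target.end, c.target.name,
            c.bait_peak.name, c.target_peak.name, c.gap, c.stratum,
        )
        for c in candidates
    ]
    pd.DataFrame(
        rows,
        columns=[
            "bait_chrom", "bait_start", "bait_end", "bait_name",
            "target_chrom", "target_start", "target_end", "target_name",
            "anchor_peak", "partner_peak", "gap", "stratum",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_loop_summary(
    path,
    bound_bait_fraction: float,
    bound_target_fraction: float,
    stratum_counts: dict[int, int],
) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "bound_bait_fraction": bound_bait_fraction,
                "bound_target_fraction": bound_target_fraction,
                "stratum_counts": {str(k): v for k, v in stratum_counts.items()},
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
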