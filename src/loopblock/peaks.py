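"""Peak and gene-model I/O plus peak-location classification.

Peaks come from ChIP experiments as BED6 or ENCODE narrowPeak; a
narrowPeak record carries the summit (offset of the highest fragment
pileup within the peak) and a signal height for it.  Gene models come
from GTF or BED12; multi-transcript genes are collapsed to the union of
their exons with the most upstream TSS.

A peak is located relative to gene anatomy using its anchor point
(summit when present, else the midpoint), tested against five mutually
exclusive categories in priority order:

    promoter        -1000..+10 bp of the TSS (strand-oriented) or 5' UTR
    distal_enhancer -2000..-1000 bp of the TSS, 3' UTR, or <=1 kb past the TES
    other           exonic
    intron          inside the gene body but not exonic
    intergenic      none of the above
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import gffutils
import pandas as pd

from .errors import ConfigurationError, FormatError, ValidationError
from .intervals import GenomicInterval

__all__ = [
    "Peak",
    "GeneModel",
    "PeakLocationCall",
    "CATEGORIES",
    "read_peaks",
    "write_peaks",
    "read_gene_models",
    "classify_peak_location",
    "peaks_to_genes",
    "write_location_calls",
]

CATEGORIES = ("promoter", "distal_enhancer", "intron", "intergenic", "other")

PROMOTER_UPSTREAM = 1000
PROMOTER_DOWNSTREAM = 10
DISTAL_UPSTREAM = 2000
DOWNSTREAM_EXTENT = 1000  # bases past the TES still counted as "downstream"


@dataclass(frozen=True)
class Peak:
    """A called peak with optional summit information."""

    interval: GenomicInterval
    summit_offset: int | None = None
    summit_height: float | None = None
    source_tf: str = ""

    def __post_init__(self) -> None:
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.interval.length
        ):
            raise ValidationError(
                f"peak {self.interval.name!r}: summit offset {self.summit_offset} "
                f"outside peak of length {self.interval.length}"
            )
        if self.summit_height is not None and self.summit_height < 0:
            raise ValidationError(
                f"peak {self.interval.name!r}: negative summit height"
            )

    @property
    def name(self) -> str:
        return self.interval.name

    @property
    def anchor(self) -> int:
        """Summit position when known, else the peak midpoint."""
        if self.summit_offset is not None:
            return self.interval.start + self.summit_offset
        return self.interval.midpoint


@dataclass(frozen=True)
class GeneModel:
    """A gene collapsed to one strand-aware model.

    ``tss``/``tes`` are single base positions consistent with the strand
    (tss > tes on the minus strand); exons are half-open, non-overlapping
    and sorted.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    exons: tuple[tuple[int, int], ...]
    five_utr: tuple[tuple[int, int], ...] = ()
    three_utr: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")
        if self.strand == "+" and self.tss > self.tes:
            raise ValidationError(f"gene {self.gene_id}: tss > tes on + strand")
        if self.strand == "-" and self.tss < self.tes:
            raise ValidationError(f"gene {self.gene_id}: tss < tes on - strand")

    @property
    def body(self) -> tuple[int, int]:
        return (min(self.tss, self.tes), max(self.tss, self.tes))


@dataclass(frozen=True)
class PeakLocationCall:
    peak: Peak
    gene_id: str | None
    category: str


# ---------------------------------------------------------------------------
# Peak I/O

def read_peaks(path, format: str = "narrowpeak", source_tf: str = "") -> list[Peak]:
    """Read peaks from ``bed6`` or ``narrowpeak`` files.

    narrowPeak: column 7 (signalValue) becomes the summit height and
    column 10 (summit offset; -1 means unknown) the summit offset.
    """
    fmt = format.lower()
    if fmt not in ("bed6", "narrowpeak"):
        raise ConfigurationError(f"unknown peak format {format!r}")
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if fmt == "narrowpeak" and df.shape[1] != 10:
        raise FormatError(f"{path}: narrowPeak requires 10 columns, got {df.shape[1]}")
    peaks: list[Peak] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            iv = GenomicInterval(
                chrom=str(row[0]),
                start=int(row[1]),
                end=int(row[2]),
                name=str(row[3]) if len(row) > 3 else "",
                score=float(row[4]) if len(row) > 4 else 0.0,
                strand=str(row[5]) if len(row) > 5 else ".",
            )
            if fmt == "narrowpeak":
                offset = int(row[9])
                signal = float(row[6])
                peaks.append(
                    Peak(
                        interval=iv,
                        summit_offset=None if offset == -1 else offset,
                        summit_height=None if signal < 0 else signal,
                        source_tf=source_tf,
                    )
                )
            else:
                peaks.append(Peak(interval=iv, source_tf=source_tf))
        except (TypeError, ValueError, ValidationError) as exc:
            raise FormatError(f"{path} line {i}: {exc}") from exc
    return peaks


def write_peaks(peaks: Iterable[Peak], path, format: str = "narrowpeak") -> None:
    fmt = format.lower()
    if fmt not in ("bed6", "narrowpeak"):
        raise ConfigurationError(f"unknown peak format {format!r}")
    rows = []
    for p in sorted(peaks, key=lambda p: p.interval.sort_key()):
        iv = p.interval
        base = [iv.chrom, iv.start, iv.end, iv.name, iv.score, iv.strand]
        if fmt == "narrowpeak":
            base += [
                p.summit_height if p.summit_height is not None else -1,
                -1,
                -1,
                p.summit_offset if p.summit_offset is not None else -1,
            ]
        rows.append(base)
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Gene models

def _collapse_gene(
    gene_id: str,
    chrom: str,
    strand: str,
    transcript_spans: list[tuple[int, int]],
    exons: list[tuple[int, int]],
    five_utr: list[tuple[int, int]],
    three_utr: list[tuple[int, int]],
) -> GeneModel:
    """Union exons; TSS is the most upstream transcript start."""
    if not transcript_spans:
        raise FormatError(f"gene {gene_id}: no transcripts or exons")
    merged: list[list[int]] = []
    for s, e in sorted(exons):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    lo = min(s for s, _ in transcript_spans)
    hi = max(e for _, e in transcript_spans)
    tss, tes = (lo, hi) if strand == "+" else (hi, lo)
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        tss=tss,
        tes=tes,
        exons=tuple(tuple(x) for x in merged),
        five_utr=tuple(sorted(five_utr)),
        three_utr=tuple(sorted(three_utr)),
    )


_FIVE_UTR_TYPES = {"five_prime_utr", "5utr", "five_prime_UTR", "5UTR"}
_THREE_UTR_TYPES = {"three_prime_utr", "3utr", "three_prime_UTR", "3UTR"}


def read_gene_models(path, format: str = "gtf") -> list[GeneModel]:
    """Read gene models from GTF (1-based inclusive, converted to 0-based
    half-open internally) or BED12."""
    fmt = format.lower()
    if fmt == "gtf":
        return _read_gtf(path)
    if fmt == "bed12":
        return _read_bed12(path)
    raise ConfigurationError(f"unknown gene-model format {format!r}")


def _read_gtf(path) -> list[GeneModel]:
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        gid = gene.attributes.get("gene_id", [gene.id])[0]
        if not gid:
            raise FormatError(f"{path}: gene feature without gene_id at line {gene.start}")
        spans: list[tuple[int, int]] = []
        exons: list[tuple[int, int]] = []
        five: list[tuple[int, int]] = []
        three: list[tuple[int, int]] = []
        for tr in db.children(gene, featuretype="transcript"):
            spans.append((tr.start - 1, tr.end))
        for child in db.children(gene):
            span = (child.start - 1, child.end)  # GTF 1-based inclusive -> half-open
            if child.featuretype == "exon":
                exons.append(span)
            elif child.featuretype in _FIVE_UTR_TYPES:
                five.append(span)
            elif child.featuretype in _THREE_UTR_TYPES:
                three.append(span)
        if not spans:
            # gene with bare exons and no transcript lines
            spans = [(gene.start - 1, gene.end)]
        if not exons:
            exons = list(spans)
        genes.append(
            _collapse_gene(gid, gene.seqid, gene.strand, spans, exons, five, three)
        )
    if not genes:
        raise FormatError(f"{path}: no gene features found")
    genes.sort(key=lambda g: (g.chrom, min(g.tss, g.tes), g.gene_id))
    return genes


def _read_bed12(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 12:
        raise FormatError(f"{path}: BED12 requires 12 columns")
    genes: list[GeneModel] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            chrom, start, end = str(row[0]), int(row[1]), int(row[2])
            name, strand = str(row[3]), str(row[5])
            sizes = [int(x) for x in str(row[10]).rstrip(",").split(",")]
            offsets = [int(x) for x in str(row[11]).rstrip(",").split(",")]
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            genes.append(
                _collapse_gene(name, chrom, strand, [(start, end)], exons, [], [])
            )
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path} line {i}: {exc}") from exc
    genes.sort(key=lambda g: (g.chrom, min(g.tss, g.tes), g.gene_id))
    return genes


# ---------------------------------------------------------------------------
# Classification

def _tss_offset(pos: int, gene: GeneModel) -> int:
    """Position of ``pos`` relative to the TSS along the direction of
    transcription (negative = upstream)."""
    return pos - gene.tss if gene.strand == "+" else gene.tss - pos


def _tes_offset(pos: int, gene: GeneModel) -> int:
    return pos - gene.tes if gene.strand == "+" else gene.tes - pos


def _categorise_against_gene(pos: int, gene: GeneModel) -> str | None:
    """Best (highest-priority) category of ``pos`` for one gene, or None."""
    d = _tss_offset(pos, gene)
    if -PROMOTER_UPSTREAM <= d <= PROMOTER_DOWNSTREAM:
        return "promoter"
    if any(s <= pos < e for s, e in gene.five_utr):
        return "promoter"
    if -DISTAL_UPSTREAM <= d < -PROMOTER_UPSTREAM:
        return "distal_enhancer"
    if any(s <= pos < e for s, e in gene.three_utr):
        return "distal_enhancer"
    e_off = _tes_offset(pos, gene)
    if 0 <= e_off <= DOWNSTREAM_EXTENT:
        return "distal_enhancer"
    lo, hi = gene.body
    if lo <= pos < hi:
        if any(s <= pos < e for s, e in gene.exons):
            return "other"
        return "intron"
    return None


_PRIORITY = {"promoter": 0, "distal_enhancer": 1, "other": 2, "intron": 3}


def classify_peak_location(
    peak: Peak, genes: Sequence[GeneModel]
) -> PeakLocationCall:
    """Classify one peak's anchor against the gene set.

    The anchor is tested against every gene; the highest-priority category
    wins (promoter > distal_enhancer > other > intron), with a positional
    tie-break among genes so the call is independent of gene-file order.
    Anchors matching nothing are intergenic, annotated with the
    nearest-TSS gene on the same chromosome when one exists.
    """
    pos = peak.anchor
    best: tuple[int, tuple, str] | None = None
    nearest: tuple[int, str] | None = None
    for gene in genes:
        if gene.chrom != peak.interval.chrom:
            continue
        dist = abs(pos - gene.tss)
        if nearest is None or (dist, gene.gene_id) < nearest:
            nearest = (dist, gene.gene_id)
        cat = _categorise_against_gene(pos, gene)
        if cat is None:
            continue
        key = (_PRIORITY[cat], (abs(pos - gene.tss), gene.gene_id))
        if best is None or key < best[:2]:
            best = (key[0], key[1], cat)
            best_gene = gene.gene_id
    if best is not None:
        return PeakLocationCall(peak=peak, gene_id=best_gene, category=best[2])
    return PeakLocationCall(
        peak=peak,
        gene_id=nearest[1] if nearest is not None else None,
        category="intergenic",
    )


def peaks_to_genes(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    max_distance: int = 50_000,
) -> dict[Peak, frozenset[str]]:
    """Map each peak to the gene(s) with the nearest TSS within
    ``max_distance`` of its anchor; equidistant TSSs are all reported."""
    if max_distance < 0:
        raise ConfigurationError("max_distance must be >= 0")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    mapping: dict[Peak, frozenset[str]] = {}
    for peak in peaks:
        pos = peak.anchor
        best_d: int | None = None
        hits: set[str] = set()
        for g in by_chrom.get(peak.interval.chrom, []):
            d = abs(pos - g.tss)
            if d > max_distance:
                continue
            if best_d is None or d < best_d:
                best_d, hits = d, {g.gene_id}
            elif d == best_d:
                hits.add(g.gene_id)
        mapping[peak] = frozenset(hits)
    return mapping


def write_location_calls(calls: Iterable[PeakLocationCall], path) -> None:
    rows = [
        (
            c.peak.interval.chrom,
            c.peak.interval.start,
            c.peak.interval.end,
            c.peak.name,
            c.category,
            c.gene_id if c.gene_id is not None else "",
        )
        for c in calls
    ]
    pd.DataFrame(
        rows, columns=["chrom", "start", "end", "peak", "category", "gene_id"]
    ).to_csv(path, sep="\t", index=False)
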