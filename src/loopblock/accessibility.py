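"""Differential chromatin-accessibility classes and coverage profiling.

Pseudo-bulk ATAC regions carry one aggregate signal per condition
(wild type vs mutant).  Each region is classified by log2 fold change
with a pseudocount:

    L = log2((mut + pc) / (wt + pc))
    gain  if L >=  threshold
    loss  if L <= -threshold
    noDA  otherwise

Pre-labelled region tables (a ``klass`` column) bypass the rule.  Peak
sets are then profiled against each class's interval union — and against
active/repressed histone-mark peaks — via base-level coverage fractions,
the per-region values behind the usual violin plots.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, replace

import pandas as pd

from .errors import ConfigurationError, ValidationError
from .intervals import GenomicInterval, IntervalSet, coverage_fraction

__all__ = [
    "ATAC_CLASSES",
    "AtacRegion",
    "CoverageProfile",
    "classify_atac",
    "group_by_class",
    "coverage_vs_classes",
    "coverage_vs_histone",
    "read_atac_table",
    "write_atac_table",
    "write_coverage_long",
]

ATAC_CLASSES = ("noDA", "loss", "gain")


@dataclass(frozen=True)
class AtacRegion:
    interval: GenomicInterval
    wt_signal: float
    mut_signal: float
    klass: str | None = None

    def __post_init__(self) -> None:
        if self.wt_signal < 0 or self.mut_signal < 0:
            raise ValidationError(
                f"ATAC region {self.interval.name!r}: negative signal"
            )
        if self.klass is not None and self.klass not in ATAC_CLASSES:
            raise ValidationError(
                f"ATAC region {self.interval.name!r}: unknown class {self.klass!r}"
            )


@dataclass(frozen=True)
class CoverageProfile:
    """Per-query-interval coverage fractions against one subject set."""

    query_label: str
    subject_label: str
    fractions: tuple[float, ...]

    def mean(self) -> float:
        return sum(self.fractions) / len(self.fractions) if self.fractions else 0.0


def classify_atac(
    regions: Iterable[AtacRegion],
    lfc_threshold: float = 1.0,
    pseudocount: float = 1.0,
) -> list[AtacRegion]:
    """Label every region noDA / loss / gain by the log-fold-change rule."""
    if lfc_threshold <= 0:
        raise ConfigurationError("lfc_threshold must be > 0")
    if pseudocount <= 0:
        raise ConfigurationError("pseudocount must be > 0")
    out: list[AtacRegion] = []
    for region in regions:
        lfc = math.log2(
            (region.mut_signal + pseudocount) / (region.wt_signal + pseudocount)
        )
        if lfc >= lfc_threshold:
            klass = "gain"
        elif lfc <= -lfc_threshold:
            klass = "loss"
        else:
            klass = "noDA"
        out.append(replace(region, klass=klass))
    return out


def group_by_class(regions: Iterable[AtacRegion]) -> dict[str, IntervalSet]:
    """Split labelled regions into one IntervalSet per class (all three
    classes always present, possibly empty)."""
    buckets: dict[str, list[GenomicInterval]] = {k: [] for k in ATAC_CLASSES}
    for region in regions:
        if region.klass is None:
            raise ValidationError(
                f"region {region.interval.name!r} is unlabelled; run classify_atac first"
            )
        buckets[region.klass].append(region.interval)
    return {k: IntervalSet(v) for k, v in buckets.items()}


def coverage_vs_classes(
    peaks: IntervalSet,
    regions_by_class: Mapping[str, IntervalSet],
    query_label: str = "peaks",
) -> dict[str, CoverageProfile]:
    """Coverage fraction of every peak against each ATAC class's union."""
    profiles: dict[str, CoverageProfile] = {}
    for klass, regions in regions_by_class.items():
        if len(regions) == 0:
            warnings.warn(f"ATAC class {klass!r} is empty", stacklevel=2)
            fracs: tuple[float, ...] = tuple(0.0 for _ in peaks)
        else:
            fracs = tuple(coverage_fraction(peaks, regions))
        profiles[klass] = CoverageProfile(
            query_label=query_label, subject_label=klass, fractions=fracs
        )
    return profiles


def coverage_vs_histone(
    peaks: IntervalSet,
    active_peaks: IntervalSet,
    repressed_peaks: IntervalSet,
    query_label: str = "peaks",
) -> tuple[CoverageProfile, CoverageProfile]:
    """Coverage of peaks against active (H3K27ac-like) and repressed
    (H3K27me3-like) histone-mark peak sets."""
    profiles = coverage_vs_classes(
        peaks,
        {"active": active_peaks, "repressed": repressed_peaks},
        query_label=query_label,
    )
    return profiles["active"], profiles["repressed"]


# ---------------------------------------------------------------------------
# I/O

def read_atac_table(path) -> list[AtacRegion]:
    """Read a tab-separated table with header
    ``chrom start end [name] wt mut [klass]``."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "wt", "mut"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    regions: list[AtacRegion] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            regions.append(
                AtacRegion(
                    interval=GenomicInterval(
                        chrom=str(d["chrom"]),
                        start=int(d["start"]),
                        end=int(d["end"]),
                        name=str(d.get("name", "")) if "name" in d else "",
                    ),
                    wt_signal=float(d["wt"]),
                    mut_signal=float(d["mut"]),
                    klass=str(d["klass"]) if "klass" in d and pd.notna(d["klass"]) else None,
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path} line {i}: {exc}") from exc
    return regions


def write_atac_table(regions: Sequence[AtacRegion], path) -> None:
    rows = [
        (
            r.interval.chrom, r.interval.start, r.interval.end, r.interval.name,
            r.wt_signal, r.mut_signal, r.klass if r.klass is not None else "",
        )
        for r in sorted(regions, key=lambda r: r.interval.sort_key())
    ]
    pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "wt", "mut", "klass"]
    ).to_csv(path, sep="\t", index=False)


def write_coverage_long(
    profiles: Iterable[CoverageProfile], peaks_by_label: Mapping[str, IntervalSet], path
) -> None:
    """Long-format (peak, subject_class, fraction) table for plotting."""
    rows = []
    for prof in profiles:
        peaks = peaks_by_label[prof.query_label]
        for iv, frac in zip(peaks, prof.fractions):
            rows.append((prof.query_label, iv.name, prof.subject_label, frac))
    pd.DataFrame(
        rows, columns=["query_set", "peak", "subject_class", "fraction"]
    ).to_csv(path, sep="\t", index=False)
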