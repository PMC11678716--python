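"""Position-specific affinity-matrix (PSAM) scanning of genomic regions.

A PSAM assigns every (position, base) a relative affinity in (0, 1],
max-normalised so the consensus window scores exactly 1.  A window's
score is the product of per-position weights — the standard biophysical
mononucleotide approximation to relative binding affinity.  Regions are
scanned on both strands at every offset and summarised by their top-k
windows, which is how candidate low-affinity binding sites (scores well
below consensus) are collected per region.

Downstream helpers compare per-region summary scores between groups
(e.g. loop-distance strata) with rank-sum tests and correlate them with
peak summit heights.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as lbstats
from .errors import DegenerateDataError, ValidationError
from .peaks import Peak

__all__ = [
    "AffinityModel",
    "WindowScore",
    "RegionAffinityProfile",
    "score_window",
    "scan_region",
    "compare_affinity_across_strata",
    "summit_affinity_correlation",
    "read_affinity_model",
    "write_affinity_model",
    "write_profiles",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = np.array([3, 2, 1, 0])  # A<->T, C<->G in ACGT index space


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an ACGTN string (case-insensitive) as int8; N -> -1."""
    table = np.full(256, -2, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    table[ord("N")] = -1
    table[ord("n")] = -1
    arr = table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if np.any(arr == -2):
        bad = seq[int(np.argmax(arr == -2))]
        raise ValidationError(f"sequence contains non-ACGTN character {bad!r}")
    return arr


@dataclass(frozen=True)
class AffinityModel:
    """Max-normalised position x base relative-affinity matrix."""

    weights: np.ndarray  # shape (length, 4), columns in ACGT order
    name: str = "model"

    @staticmethod
    def from_weights(weights, name: str = "model") -> "AffinityModel":
        w = np.asarray(weights, dtype=float)
        if w.ndim != 2 or w.shape[1] != 4 or w.shape[0] < 1:
            raise ValidationError("affinity weights must have shape (length, 4)")
        if np.any(~np.isfinite(w)) or np.any(w <= 0):
            raise ValidationError("affinity weights must be positive and finite")
        maxima = w.max(axis=1)
        if not np.allclose(maxima, 1.0):
            warnings.warn(
                f"affinity model {name!r}: per-position maxima != 1; renormalising",
                stacklevel=2,
            )
            w = w / maxima[:, None]
        w = w.copy()
        w.setflags(write=False)
        return AffinityModel(weights=w, name=name)

    @property
    def length(self) -> int:
        return self.weights.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.weights.argmax(axis=1))

    def reverse_complement(self) -> "AffinityModel":
        rc = self.weights[::-1, ::-1].copy()
        rc.setflags(write=False)
        return AffinityModel(weights=rc, name=self.name + "_rc")


@dataclass(frozen=True)
class WindowScore:
    region_id: str
    offset: int
    strand: str
    score: float


@dataclass(frozen=True)
class RegionAffinityProfile:
    """Top-k affinity windows of one region, descending by score.

    ``summary_score`` is the mean of the retained window scores (NaN when
    every window was masked, e.g. an all-N region).
    """

    region_id: str
    top_windows: tuple[WindowScore, ...]
    summary_score: float


def score_window(seq: str, model: AffinityModel) -> float:
    """Score a single window of exactly model length; any N gives 0."""
    if len(seq) != model.length:
        raise ValidationError(
            f"window length {len(seq)} != model length {model.length}"
        )
    idx = encode_sequence(seq)
    if np.any(idx < 0):
        return 0.0
    return float(np.prod(model.weights[np.arange(model.length), idx]))


def _window_scores(idx: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Scores of all sliding windows of an encoded sequence (vectorised).
    Windows containing N come back as NaN."""
    L = weights.shape[0]
    wins = np.lib.stride_tricks.sliding_window_view(idx, L)
    valid = np.all(wins >= 0, axis=1)
    safe = np.where(wins < 0, 0, wins)
    gathered = weights[np.arange(L)[None, :], safe]
    scores = gathered.prod(axis=1)
    scores[~valid] = np.nan
    return scores


def scan_region(
    region_id: str, region_seq: str, model: AffinityModel, k: int = 10
) -> RegionAffinityProfile:
    """Scan every offset of a region on both strands and keep the top-k windows.

    The score at an offset is the larger of the forward score and the
    reverse-complement score (ties go to the + strand).  Windows containing
    N never enter the ranking.  Ties between offsets are broken by smaller
    offset.
    """
    if len(region_seq) < model.length:
        raise ValidationError(
            f"region {region_id!r} (length {len(region_seq)}) shorter than "
            f"model (length {model.length})"
        )
    if k < 1:
        raise ValidationError("k must be >= 1")
    idx = encode_sequence(region_seq)
    fwd = _window_scores(idx, model.weights)
    rev = _window_scores(idx, model.reverse_complement().weights)
    with np.errstate(invalid="ignore"):
        use_rev = rev > fwd
    best = np.where(use_rev, rev, fwd)
    valid = np.where(~np.isnan(best))[0]
    if valid.size == 0:
        return RegionAffinityProfile(region_id, (), float("nan"))
    order = valid[np.lexsort((use_rev[valid], valid, -best[valid]))]
    top = order[:k]
    windows = tuple(
        WindowScore(
            region_id=region_id,
            offset=int(o),
            strand="-" if use_rev[o] else "+",
            score=float(best[o]),
        )
        for o in top
    )
    return RegionAffinityProfile(
        region_id=region_id,
        top_windows=windows,
        summary_score=float(np.mean([w.score for w in windows])),
    )


def _summaries(group) -> list[float]:
    out = []
    for item in group:
        if isinstance(item, RegionAffinityProfile):
            out.append(item.summary_score)
        else:
            out.append(float(item))
    return [v for v in out if not np.isnan(v)]


def compare_affinity_across_strata(
    groups: Mapping[str, Sequence],
    reference_groups: Mapping[str, Sequence[float]] | None = None,
) -> pd.DataFrame:
    """Pairwise two-sided rank-sum comparisons of per-region summary scores.

    ``groups`` maps a label (e.g. a stratum bound) to profiles or raw
    scores; ``reference_groups`` adds named score sets (e.g. known-motif
    affinities) to the comparison.  Groups with fewer than two members are
    excluded with a warning.  Returns a table with one row per pair.
    """
    all_groups: dict[str, list[float]] = {
        str(k): _summaries(v) for k, v in groups.items()
    }
    for k, v in (reference_groups or {}).items():
        all_groups[str(k)] = [float(x) for x in v]
    usable: dict[str, list[float]] = {}
    for label, values in all_groups.items():
        if len(values) < 2:
            warnings.warn(
                f"group {label!r} has fewer than 2 members; excluded", stacklevel=2
            )
            continue
        usable[label] = values
    if len(usable) < 2:
        raise DegenerateDataError("need at least two groups with >= 2 members")
    labels = list(usable)
    rows = []
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            res = lbstats.wilcoxon_rank_sum(usable[la], usable[lb], "two-sided")
            rows.append(
                (la, lb, res.n1, res.n2, res.statistic, res.p_value, res.method)
            )
    return pd.DataFrame(
        rows,
        columns=["group_a", "group_b", "n_a", "n_b", "statistic", "p_value", "method"],
    )


def summit_affinity_correlation(
    peaks: Sequence[Peak],
    profiles: Sequence[RegionAffinityProfile],
) -> tuple[float, int]:
    """Pearson correlation between peak summit heights and the summary
    scores of the profiles they match (by peak name == region_id)."""
    by_region = {p.region_id: p for p in profiles}
    heights: list[float] = []
    scores: list[float] = []
    for peak in peaks:
        prof = by_region.get(peak.name)
        if prof is None or peak.summit_height is None:
            continue
        if np.isnan(prof.summary_score):
            continue
        heights.append(peak.summit_height)
        scores.append(prof.summary_score)
    if len(heights) < 3:
        raise DegenerateDataError(
            f"summit_affinity_correlation: only {len(heights)} matched pairs (need >= 3)"
        )
    return lbstats.pearson(heights, scores)


# ---------------------------------------------------------------------------
# I/O

def read_affinity_model(path, name: str | None = None) -> AffinityModel:
    """Read a TSV of columns position, A, C, G, T (one row per position)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("position", *BASES) if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    df = df.sort_values("position")
    return AffinityModel.from_weights(
        df[list(BASES)].to_numpy(dtype=float),
        name=name if name is not None else str(path),
    )


def write_affinity_model(model: AffinityModel, path) -> None:
    df = pd.DataFrame(model.weights, columns=list(BASES))
    df.insert(0, "position", np.arange(model.length))
    df.to_csv(path, sep="\t", index=False)


def write_profiles(profiles: Iterable[RegionAffinityProfile], path) -> None:
    rows = []
    for prof in profiles:
        for rank, w in enumerate(prof.top_windows, start=1):
            rows.append((prof.region_id, w.offset, w.strand, w.score, rank))
    pd.DataFrame(
        rows, columns=["region_id", "offset", "strand", "score", "rank"]
    ).to_csv(path, sep="\t", index=False)
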