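"""Seeded synthetic input bundles with planted ground truth.

The generator emulates the *structure* of a mesodermal TF-blocking
analysis: a capture catalogue of ~600 promoter-proximal baits and
~20,000 distal targets of which ~10% carry anchor-TF (Hox-like) or
partner-TF (Mef2-like) peaks respectively; loop distances spanning
0-50 kb strata; planted low-affinity binding sites whose mean relative
affinity decreases with loop distance; summit heights positively coupled
to planted affinity; three differential-accessibility classes; and
active/repressed histone-mark peaks covering a configurable open
fraction of bound regions.

Geometry.  Each bound bait lives in its own "loop block": the bait plus
its bound targets, the nearest of which sits in the bait's assigned
distance stratum.  Blocks are spaced further apart than the largest
stratum bound, so the planted pair set is exactly what a window join at
the largest bound discovers.  Unbound decoy baits/targets, genes and
spare ATAC regions live in a free zone beyond the blocks, more than one
window width away from any planted peak.

Everything is drawn from one seeded generator in a fixed order, so a
bundle is byte-reproducible per seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .affinity import BASES, AffinityModel, write_affinity_model
from .accessibility import ATAC_CLASSES, AtacRegion, classify_atac, write_atac_table
from .errors import ConfigurationError, ValidationError
from .intervals import GenomicInterval, write_bed
from .peaks import Peak, write_peaks

__all__ = ["SimulationConfig", "GroundTruth", "generate_bundle", "degrade_consensus"]

_MAX_PLANT_MISMATCHES = 3  # keeps planted sites above typical background windows


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic bundle.

    Defaults mirror the structure of the real inputs: 600 baits, 20,000
    targets, 10% bound on each side, 0-50 kb strata, per-stratum mean
    site affinity strictly decreasing with distance, and a mostly-open
    chromatin landscape.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 300
    n_baits: int = 600
    n_targets: int = 20_000
    bound_bait_fraction: float = 0.10
    bound_target_fraction: float = 0.10
    strata_bounds: tuple[int, ...] = (0, 10_000, 20_000, 30_000, 40_000, 50_000)
    affinity_decay: tuple[float, ...] = (0.90, 0.55, 0.35, 0.20, 0.12, 0.06)
    atac_class_proportions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    open_fraction: float = 0.90
    consensus: str = "TTAATTACGGTC"
    mismatch_penalty: float = 0.30
    bait_length: int = 400
    target_length: int = 300
    sites_per_bait: int = 10
    n_atac_regions: int = 3_000
    summit_base: float = 50.0
    summit_scale: float = 400.0
    summit_noise_sd: float = 60.0

    def __post_init__(self) -> None:
        for name in ("bound_bait_fraction", "bound_target_fraction", "open_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        self.strata_bounds = tuple(int(b) for b in self.strata_bounds)
        if any(b2 <= b1 for b1, b2 in zip(self.strata_bounds, self.strata_bounds[1:])):
            raise ConfigurationError("strata_bounds must be strictly increasing")
        self.affinity_decay = tuple(float(x) for x in self.affinity_decay)
        if len(self.affinity_decay) != len(self.strata_bounds):
            raise ConfigurationError(
                "affinity_decay must give one mean score per stratum"
            )
        if any(
            d2 >= d1 for d1, d2 in zip(self.affinity_decay, self.affinity_decay[1:])
        ):
            raise ConfigurationError("affinity_decay must be strictly decreasing")
        if any(not (0 < d <= 1) for d in self.affinity_decay):
            raise ConfigurationError("affinity_decay values must lie in (0, 1]")
        self.atac_class_proportions = tuple(float(x) for x in self.atac_class_proportions)
        if len(self.atac_class_proportions) != 3 or not np.isclose(
            sum(self.atac_class_proportions), 1.0
        ):
            raise ConfigurationError("atac_class_proportions must be 3 values summing to 1")
        if not (0 < self.mismatch_penalty < 1):
            raise ConfigurationError("mismatch_penalty must lie in (0, 1)")
        if set(self.consensus.upper()) - set(BASES):
            raise ConfigurationError("consensus must be an ACGT string")
        if self.bait_length < self.sites_per_bait * (len(self.consensus) + 2):
            raise ConfigurationError("bait_length too short for the planted sites")

    @classmethod
    def tiny(cls, seed: int = 0) -> "SimulationConfig":
        """A reduced profile for unit tests: one 1 Mb chromosome, 20 baits,
        200 targets, higher bound fractions so every stratum is populated."""
        return cls(
            seed=seed,
            n_chromosomes=1,
            chrom_length=1_000_000,
            n_genes=20,
            n_baits=20,
            n_targets=200,
            bound_bait_fraction=0.30,
            bound_target_fraction=0.15,
            n_atac_regions=120,
        )


@dataclass
class GroundTruth:
    """Planted structure of a bundle, mirrored in ``truth.json``."""

    bound_baits: list[str]
    bound_targets: list[str]
    loops: list[dict]  # {"bait", "target", "gap", "stratum"}
    bait_stratum: dict[str, int]
    site_offsets: dict[str, list[int]]
    site_mismatches: dict[str, list[int]]
    expected_summary: dict[str, float]
    summit_heights: dict[str, float]
    atac_labels: dict[str, str]
    histone_open: dict[str, bool]
    files: dict[str, str] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def degrade_consensus(
    consensus: str,
    target_score: float,
    mismatch_penalty: float,
    rng: np.random.Generator,
) -> str:
    """Introduce the minimal number of mismatches m such that
    ``penalty**m <= target_score < penalty**(m-1)``; mismatch positions
    and substituted bases are drawn from ``rng``."""
    if not (0 < target_score <= 1):
        raise ValidationError(f"target_score must lie in (0, 1], got {target_score}")
    if not (0 < mismatch_penalty < 1):
        raise ValidationError("mismatch_penalty must lie in (0, 1)")
    m = 0
    # relative tolerance absorbs float drift, e.g. 0.1**2 vs a literal 0.01
    while mismatch_penalty**m > target_score * (1 + 1e-9):
        m += 1
        if m > len(consensus):
            raise ValidationError(
                f"target score {target_score} unreachable with penalty "
                f"{mismatch_penalty} over {len(consensus)} positions"
            )
    if m == 0:
        return consensus
    positions = rng.choice(len(consensus), size=m, replace=False)
    seq = list(consensus)
    for pos in positions:
        alternatives = [b for b in BASES if b != consensus[pos]]
        seq[pos] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(seq)


def _site_composition(
    target_mean: float, n_sites: int, penalty: float
) -> list[int]:
    """Mismatch counts for ``n_sites`` planted sites whose mean score
    (penalty**m each) is closest to ``target_mean``.  Deterministic."""
    levels = [penalty**m for m in range(_MAX_PLANT_MISMATCHES + 1)]
    best: tuple[float, tuple[int, ...]] | None = None
    for n0 in range(n_sites + 1):
        for n1 in range(n_sites - n0 + 1):
            for n2 in range(n_sites - n0 - n1 + 1):
                n3 = n_sites - n0 - n1 - n2
                counts = (n0, n1, n2, n3)
                mean = sum(c * l for c, l in zip(counts, levels)) / n_sites
                key = (abs(mean - target_mean), counts)
                if best is None or key < best:
                    best = key
    counts = best[1]
    out: list[int] = []
    for m, c in enumerate(counts):
        out.extend([m] * c)
    return out


def _consensus_model(consensus: str, penalty: float) -> AffinityModel:
    w = np.full((len(consensus), 4), penalty)
    for i, base in enumerate(consensus):
        w[i, BASES.index(base)] = 1.0
    return AffinityModel.from_weights(w, name="planted_consensus")


def _random_interval(
    rng: np.random.Generator, chrom: str, zone: tuple[int, int], length: int
) -> tuple[str, int, int]:
    lo, hi = zone
    start = int(rng.integers(lo, max(lo + 1, hi - length)))
    return chrom, start, start + length


def generate_bundle(config: SimulationConfig, out_dir) -> GroundTruth:
    """Write a complete synthetic input bundle to ``out_dir`` and return
    its ground truth (also saved as ``truth.json``)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    L = len(config.consensus)
    max_bound = config.strata_bounds[-1]
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]

    # background genome, one int8 array (ACGT = 0..3) per chromosome
    genome = {c: rng.integers(0, 4, size=config.chrom_length, dtype=np.int8) for c in chroms}

    # --- loop blocks -------------------------------------------------------
    n_bound_baits = int(round(config.n_baits * config.bound_bait_fraction))
    n_bound_targets = int(round(config.n_targets * config.bound_target_fraction))
    pitch = 2 * max_bound + config.bait_length + config.target_length + 20_000
    per_chrom = -(-n_bound_baits // config.n_chromosomes)  # ceil
    if per_chrom * pitch + pitch > config.chrom_length:
        raise ConfigurationError(
            f"chrom_length {config.chrom_length} too short for {per_chrom} "
            f"loop blocks of pitch {pitch}"
        )

    baits: list[GenomicInterval] = []
    targets: list[GenomicInterval] = []
    anchor_peaks: list[Peak] = []
    partner_peaks: list[Peak] = []
    truth_bait_stratum: dict[str, int] = {}
    site_offsets: dict[str, list[int]] = {}
    site_mismatches: dict[str, list[int]] = {}
    expected_summary: dict[str, float] = {}
    summit_heights: dict[str, float] = {}

    compositions = {
        bound: _site_composition(mean, config.sites_per_bait, config.mismatch_penalty)
        for bound, mean in zip(config.strata_bounds, config.affinity_decay)
    }

    target_counts = np.full(n_bound_baits, n_bound_targets // max(1, n_bound_baits))
    target_counts[: n_bound_targets - int(target_counts.sum())] += 1

    target_idx = 0
    block_ends = {c: 0 for c in chroms}
    for i in range(n_bound_baits):
        chrom = chroms[i // per_chrom]
        block_start = (i % per_chrom) * pitch + 10_000
        bstart = block_start
        bait = GenomicInterval(
            chrom, bstart, bstart + config.bait_length, name=f"bait_{i:05d}"
        )
        baits.append(bait)
        s_idx = i % len(config.strata_bounds)
        bound = config.strata_bounds[s_idx]
        prev = config.strata_bounds[s_idx - 1] if s_idx > 0 else None
        truth_bait_stratum[bait.name] = bound

        # bound targets for this bait; the first pins the bait's stratum
        n_t = int(target_counts[i])
        for j in range(n_t):
            if bound == 0 and j == 0:
                tstart = bait.start + int(
                    rng.integers(0, max(1, config.bait_length - 50))
                )
            elif j == 0:
                gap = int(rng.integers(prev + 1, bound + 1))
                tstart = bait.end + gap
            else:
                low = 0 if bound == 0 else prev + 1
                gap = int(rng.integers(low, max_bound + 1))
                tstart = bait.end + gap
            target = GenomicInterval(
                chrom,
                tstart,
                tstart + config.target_length,
                name=f"target_{target_idx:05d}",
            )
            target_idx += 1
            targets.append(target)
            height = float(max(1.0, rng.normal(80.0, 10.0)))
            partner_peaks.append(
                Peak(
                    interval=GenomicInterval(
                        target.chrom,
                        target.start + int(rng.integers(0, 30)),
                        target.end - int(rng.integers(0, 30)),
                        name=f"partner_{target.name}",
                        score=min(1000.0, round(height)),
                    ),
                    summit_offset=None,
                    summit_height=round(height, 2),
                    source_tf="partner",
                )
            )
        block_ends[chrom] = max(block_ends[chrom], bait.end + max_bound + config.target_length)

        # planted low-affinity sites inside the bait region
        mismatches = list(rng.permutation(compositions[bound]))
        mismatches = [int(m) for m in mismatches]
        slot = config.bait_length // config.sites_per_bait
        offsets: list[int] = []
        for k, m in enumerate(mismatches):
            off = k * slot + int(rng.integers(0, max(1, slot - L)))
            site = degrade_consensus(
                config.consensus, config.mismatch_penalty**m, config.mismatch_penalty, rng
            )
            enc = np.array([BASES.index(b) for b in site], dtype=np.int8)
            genome[chrom][bait.start + off : bait.start + off + L] = enc
            offsets.append(off)
        site_offsets[bait.name] = offsets
        site_mismatches[bait.name] = mismatches
        mean_score = float(
            np.mean([config.mismatch_penalty**m for m in mismatches])
        )
        expected_summary[bait.name] = mean_score

        best = min(range(len(mismatches)), key=lambda k: (mismatches[k], k))
        peak_start = bait.start + int(rng.integers(0, 20))
        peak_end = bait.end - int(rng.integers(0, 20))
        summit_offset = offsets[best] + L // 2 - (peak_start - bait.start)
        summit_offset = max(0, min(summit_offset, peak_end - peak_start - 1))
        height = float(
            max(
                1.0,
                config.summit_base
                + config.summit_scale * mean_score
                + rng.normal(0.0, config.summit_noise_sd),
            )
        )
        summit_heights[bait.name] = round(height, 2)
        anchor_peaks.append(
            Peak(
                interval=GenomicInterval(
                    chrom, peak_start, peak_end,
                    name=f"anchor_{bait.name}",
                    score=min(1000.0, round(height)),
                ),
                summit_offset=summit_offset,
                summit_height=round(height, 2),
                source_tf="anchor",
            )
        )

    # --- decoys, genes, extra ATAC in the free zone ------------------------
    free_zones = {
        c: (block_ends[c] + max_bound + 10_000, config.chrom_length - 1_000)
        for c in chroms
    }
    for c, (lo, hi) in free_zones.items():
        if hi - lo < 50_000:
            raise ConfigurationError(
                f"no free zone left on {c}; increase chrom_length"
            )

    def free_chrom() -> str:
        return chroms[int(rng.integers(len(chroms)))]

    for i in range(config.n_baits - n_bound_baits):
        c = free_chrom()
        chrom, s, e = _random_interval(rng, c, free_zones[c], config.bait_length)
        baits.append(
            GenomicInterval(chrom, s, e, name=f"bait_{n_bound_baits + i:05d}")
        )
    for i in range(config.n_targets - n_bound_targets):
        c = free_chrom()
        chrom, s, e = _random_interval(rng, c, free_zones[c], config.target_length)
        targets.append(
            GenomicInterval(chrom, s, e, name=f"target_{n_bound_targets + i:05d}")
        )

    gtf_lines: list[str] = []
    for i in range(config.n_genes):
        c = free_chrom()
        span = int(rng.integers(2_000, 8_000))
        chrom, s, e = _random_interval(rng, c, free_zones[c], span)
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"gene_{i:04d}"
        n_exons = int(rng.integers(1, 4))
        cuts = sorted(rng.integers(200, span - 200, size=2 * (n_exons - 1)).tolist())
        edges = [0, *cuts, span]
        exons = [
            (s + edges[2 * k], s + edges[2 * k + 1]) for k in range(n_exons)
        ]
        attrs = f'gene_id "{gid}"; transcript_id "{gid}.t1";'
        gtf_lines.append(
            f'{chrom}\tsim\tgene\t{s + 1}\t{e}\t.\t{strand}\t.\tgene_id "{gid}";'
        )
        gtf_lines.append(
            f"{chrom}\tsim\ttranscript\t{s + 1}\t{e}\t.\t{strand}\t.\t{attrs}"
        )
        for xs, xe in exons:
            gtf_lines.append(
                f"{chrom}\tsim\texon\t{xs + 1}\t{xe}\t.\t{strand}\t.\t{attrs}"
            )

    # --- ATAC regions ------------------------------------------------------
    atac_regions: list[AtacRegion] = []
    atac_labels: dict[str, str] = {}
    klass_draw = lambda: ATAC_CLASSES[
        int(rng.choice(3, p=list(config.atac_class_proportions)))
    ]

    def make_atac(name: str, chrom: str, start: int, end: int, klass: str) -> None:
        wt = int(rng.integers(50, 201))
        if klass == "noDA":
            u = rng.uniform(-0.4, 0.4)
        elif klass == "loss":
            u = rng.uniform(-3.0, -1.6)
        else:
            u = rng.uniform(1.6, 3.0)
        mut = max(0, int(round((wt + 1.0) * 2.0**u - 1.0)))
        atac_regions.append(
            AtacRegion(
                interval=GenomicInterval(chrom, start, end, name=name),
                wt_signal=wt,
                mut_signal=mut,
            )
        )

    covered = baits[:n_bound_baits] + targets[:n_bound_targets]
    for i, iv in enumerate(covered):
        make_atac(
            f"atac_{i:05d}", iv.chrom, max(0, iv.start - 100), iv.end + 100, klass_draw()
        )
    for i in range(len(covered), config.n_atac_regions):
        c = free_chrom()
        chrom, s, e = _random_interval(rng, c, free_zones[c], 500)
        make_atac(f"atac_{i:05d}", chrom, s, e, klass_draw())
    # the realised labels are what the classification rule yields on the
    # written counts, so truth and pipeline agree exactly
    atac_regions = classify_atac(atac_regions, lfc_threshold=1.0, pseudocount=1.0)
    for region in atac_regions:
        atac_labels[region.interval.name] = region.klass

    # --- histone marks -----------------------------------------------------
    active: list[GenomicInterval] = []
    repressed: list[GenomicInterval] = []
    histone_open: dict[str, bool] = {}
    for iv in covered:
        is_open = bool(rng.random() < config.open_fraction)
        histone_open[iv.name] = is_open
        mark = GenomicInterval(
            iv.chrom,
            max(0, iv.start - 200),
            iv.end + 200,
            name=f"{'ac' if is_open else 'me'}_{iv.name}",
        )
        (active if is_open else repressed).append(mark)
    for i in range(200):
        c = free_chrom()
        chrom, s, e = _random_interval(rng, c, free_zones[c], 800)
        lst = active if rng.random() < config.open_fraction else repressed
        lst.append(GenomicInterval(chrom, s, e, name=f"extra_mark_{i:04d}"))

    # --- planted-loop truth (independent brute force over bound sets) ------
    loops: list[dict] = []
    bounds = config.strata_bounds
    for bait in baits[:n_bound_baits]:
        for target in targets[:n_bound_targets]:
            if bait.chrom != target.chrom:
                continue
            g = max(0, max(bait.start, target.start) - min(bait.end, target.end))
            if g > max_bound:
                continue
            stratum = next(b for b in bounds if g <= b)
            loops.append(
                {"bait": bait.name, "target": target.name, "gap": g, "stratum": stratum}
            )
    loops.sort(key=lambda d: (d["bait"], d["target"]))

    # --- write files -------------------------------------------------------
    files = {
        "genome": "genome.fa",
        "genes": "genes.gtf",
        "baits": "baits.bed",
        "targets": "targets.bed",
        "anchor_peaks": "anchor_peaks.narrowPeak",
        "partner_peaks": "partner_peaks.narrowPeak",
        "atac": "atac_signal.tsv",
        "histone_active": "histone_active.bed",
        "histone_repressed": "histone_repressed.bed",
        "affinity_model": "affinity_model.tsv",
        "truth": "truth.json",
        "config": "config.yaml",
    }
    _write_fasta(genome, chroms, out / files["genome"])
    (out / files["genes"]).write_text("\n".join(gtf_lines) + "\n")
    write_bed(baits, out / files["baits"])
    write_bed(targets, out / files["targets"])
    write_peaks(anchor_peaks, out / files["anchor_peaks"], format="narrowpeak")
    write_peaks(partner_peaks, out / files["partner_peaks"], format="narrowpeak")
    write_atac_table(atac_regions, out / files["atac"])
    write_bed(active, out / files["histone_active"])
    write_bed(repressed, out / files["histone_repressed"])
    write_affinity_model(
        _consensus_model(config.consensus, config.mismatch_penalty),
        out / files["affinity_model"],
    )
    with open(out / files["config"], "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)

    truth = GroundTruth(
        bound_baits=[b.name for b in baits[:n_bound_baits]],
        bound_targets=[t.name for t in targets[:n_bound_targets]],
        loops=loops,
        bait_stratum=truth_bait_stratum,
        site_offsets=site_offsets,
        site_mismatches=site_mismatches,
        expected_summary=expected_summary,
        summit_heights=summit_heights,
        atac_labels=atac_labels,
        histone_open=histone_open,
        files=files,
    )
    truth.to_json(out / files["truth"])
    return truth


def _write_fasta(genome: dict, chroms: list[str], path, width: int = 80) -> None:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    with open(path, "w") as fh:
        for c in chroms:
            fh.write(f">{c}\n")
            seq = lut[genome[c]].tobytes().decode("ascii")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width])
                fh.write("\n")
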