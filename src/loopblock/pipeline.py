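"""End-to-end orchestration: from input files to loop candidates,
affinity comparisons, accessibility and histone coverage, and a JSON
run report.

Every stage is a thin call into the corresponding library module; the
pipeline only wires stages together, writes the tabular outputs, and
collects the report.  All outputs are deterministic functions of the
inputs (no timestamps, no unseeded randomness), so identical runs are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pyfaidx
import yaml
from scipy import stats as sps

from . import __version__
from .accessibility import (
    classify_atac,
    coverage_vs_classes,
    coverage_vs_histone,
    group_by_class,
    read_atac_table,
    write_coverage_long,
)
from .affinity import (
    compare_affinity_across_strata,
    read_affinity_model,
    scan_region,
    summit_affinity_correlation,
    write_profiles,
)
from .errors import ConfigurationError
from .intervals import IntervalSet, read_bed
from .loops import (
    associate_anchor_peaks,
    associate_target_peaks,
    build_loop_candidates,
    peak_and_gene_overlap,
    write_candidates,
    write_loop_summary,
)
from .peaks import (
    classify_peak_location,
    read_gene_models,
    read_peaks,
    write_location_calls,
)
from .simulate import SimulationConfig, generate_bundle
from .stats import benjamini_hochberg

__all__ = ["PipelineConfig", "RunReport", "run_simulate", "run_analysis"]

DEFAULT_BOUNDS = (0, 10_000, 20_000, 30_000, 40_000, 50_000)


@dataclass
class PipelineConfig:
    """Paths and parameters for one analysis run.

    ``genes``, ``atac`` and the histone paths are optional; the
    corresponding stages are skipped when absent.
    """

    baits: str
    targets: str
    anchor_peaks: str
    partner_peaks: str
    genome: str
    affinity_model: str
    out_dir: str
    genes: str | None = None
    atac: str | None = None
    histone_active: str | None = None
    histone_repressed: str | None = None
    strata_bounds: tuple[int, ...] = DEFAULT_BOUNDS
    k_windows: int = 10
    lfc_threshold: float = 1.0
    pseudocount: float = 1.0
    anchor_label: str = "anchor"
    partner_label: str = "partner"
    seed: int = 0

    def __post_init__(self) -> None:
        self.strata_bounds = tuple(int(b) for b in self.strata_bounds)
        if self.k_windows < 1:
            raise ConfigurationError("k_windows must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    @classmethod
    def from_bundle(cls, bundle_dir, out_dir, **overrides) -> "PipelineConfig":
        """Configuration pointing at a synthetic bundle directory."""
        b = Path(bundle_dir)
        kwargs = dict(
            baits=str(b / "baits.bed"),
            targets=str(b / "targets.bed"),
            anchor_peaks=str(b / "anchor_peaks.narrowPeak"),
            partner_peaks=str(b / "partner_peaks.narrowPeak"),
            genome=str(b / "genome.fa"),
            affinity_model=str(b / "affinity_model.tsv"),
            genes=str(b / "genes.gtf"),
            atac=str(b / "atac_signal.tsv"),
            histone_active=str(b / "histone_active.bed"),
            histone_repressed=str(b / "histone_repressed.bed"),
            out_dir=str(out_dir),
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    _PATH_FIELDS = (
        "baits", "targets", "anchor_peaks", "partner_peaks", "genome",
        "affinity_model", "genes", "atac", "histone_active",
        "histone_repressed",
    )

    def sha256(self) -> str:
        """Digest of the analysis parameters; input path fields contribute
        their basenames only and the output directory is excluded, so
        identical runs in different directories share a provenance hash."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)
        for key in self._PATH_FIELDS:
            if payload.get(key) is not None:
                payload[key] = Path(payload[key]).name
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()


@dataclass
class RunReport:
    """Aggregate numbers of one run; every entry is recomputable from the
    TSVs written next to it."""

    bound_bait_fraction: float
    bound_target_fraction: float
    n_bound_baits: int
    n_bound_targets: int
    n_candidates: int
    stratum_counts: dict[str, int]
    bait_min_stratum: dict[str, int]
    affinity_comparisons: list[dict] = field(default_factory=list)
    stratum_median_affinity: dict[str, float] = field(default_factory=dict)
    affinity_distance_rank_corr: float | None = None
    summit_affinity_r: float | None = None
    summit_affinity_n: int = 0
    atac_class_counts: dict[str, int] = field(default_factory=dict)
    atac_labels: dict[str, str] = field(default_factory=dict)
    coverage_means: dict[str, float] = field(default_factory=dict)
    peak_overlap: dict[str, int] = field(default_factory=dict)
    gene_overlap: dict[str, int] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_simulate(config: SimulationConfig, out_dir):
    """Generate a synthetic bundle (delegates to the generator)."""
    return generate_bundle(config, out_dir)


def run_analysis(cfg: PipelineConfig) -> RunReport:
    """Execute the full analysis and write all outputs under ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    baits = read_bed(cfg.baits)
    targets = read_bed(cfg.targets)
    anchor_peaks = read_peaks(cfg.anchor_peaks, "narrowpeak", source_tf=cfg.anchor_label)
    partner_peaks = read_peaks(cfg.partner_peaks, "narrowpeak", source_tf=cfg.partner_label)

    # --- association and loop candidates ----------------------------------
    bound_baits, frac_baits = associate_anchor_peaks(anchor_peaks, baits)
    bound_targets, frac_targets = associate_target_peaks(partner_peaks, targets)
    candidates = build_loop_candidates(
        bound_baits, bound_targets, anchor_peaks, partner_peaks, cfg.strata_bounds
    )
    write_candidates(candidates, out / "loop_candidates.tsv")
    stratum_counts: dict[str, int] = {str(b): 0 for b in cfg.strata_bounds}
    bait_min_stratum: dict[str, int] = {}
    for c in candidates:
        stratum_counts[str(c.stratum)] += 1
        prev = bait_min_stratum.get(c.bait.name)
        if prev is None or c.stratum < prev:
            bait_min_stratum[c.bait.name] = c.stratum
    write_loop_summary(
        out / "loop_summary.json", frac_baits, frac_targets,
        {b: stratum_counts[str(b)] for b in cfg.strata_bounds},
    )

    report = RunReport(
        bound_bait_fraction=frac_baits,
        bound_target_fraction=frac_targets,
        n_bound_baits=len(bound_baits),
        n_bound_targets=len(bound_targets),
        n_candidates=len(candidates),
        stratum_counts=stratum_counts,
        bait_min_stratum=bait_min_stratum,
    )

    # --- peak locations and Venn summaries --------------------------------
    if cfg.genes is not None:
        genes = read_gene_models(cfg.genes, "gtf")
        calls = [
            classify_peak_location(p, genes) for p in anchor_peaks + partner_peaks
        ]
        write_location_calls(calls, out / "peak_locations.tsv")
        peak_level, gene_level = peak_and_gene_overlap(
            anchor_peaks, partner_peaks, genes
        )
        report.peak_overlap = {
            "a_only": peak_level.n_a_only,
            "b_only": peak_level.n_b_only,
            "common": peak_level.n_common,
        }
        report.gene_overlap = {
            "a_only": gene_level.n_a_only,
            "b_only": gene_level.n_b_only,
            "common": gene_level.n_common,
        }

    # --- affinity scanning over bound bait regions -------------------------
    model = read_affinity_model(cfg.affinity_model, name="anchor_model")
    fasta = pyfaidx.Fasta(cfg.genome)
    profiles = []
    for bait in bound_baits:
        seq = str(fasta[bait.chrom][bait.start : bait.end])
        profiles.append(scan_region(bait.name, seq, model, k=cfg.k_windows))
    write_profiles(profiles, out / "affinity_profiles.tsv")
    _export_fasta(bound_baits, fasta, out / "bait_regions.fa")

    groups: dict[str, list] = {}
    for prof in profiles:
        stratum = bait_min_stratum.get(prof.region_id)
        if stratum is None:
            continue
        groups.setdefault(str(stratum), []).append(prof)
    groups = {k: groups[k] for k in sorted(groups, key=int)}
    if len([g for g in groups.values() if len(g) >= 2]) >= 2:
        table = compare_affinity_across_strata(groups)
        table["p_adjusted"] = benjamini_hochberg(table["p_value"].to_numpy())
        table.to_csv(out / "affinity_comparisons.tsv", sep="\t", index=False)
        report.affinity_comparisons = table.to_dict(orient="records")
    medians = {
        k: float(np.median([p.summary_score for p in v])) for k, v in groups.items()
    }
    report.stratum_median_affinity = medians
    if len(medians) >= 3:
        rho = sps.spearmanr(
            [int(k) for k in medians], list(medians.values())
        ).statistic
        report.affinity_distance_rank_corr = float(rho)

    peak_by_bait = {}
    for c in candidates:
        peak_by_bait.setdefault(c.bait.name, c.bait_peak)
    matched_peaks = [
        dataclasses.replace(
            p, interval=dataclasses.replace(p.interval, name=bait_name)
        )
        for bait_name, p in peak_by_bait.items()
    ]
    if len(matched_peaks) >= 3:
        r, n = summit_affinity_correlation(matched_peaks, profiles)
        report.summit_affinity_r = r
        report.summit_affinity_n = n

    # --- accessibility and histone context ---------------------------------
    peaks_by_label = {
        "bound_baits": bound_baits,
        "bound_targets": bound_targets,
    }
    long_profiles = []
    if cfg.atac is not None:
        regions = read_atac_table(cfg.atac)
        if any(r.klass is None for r in regions):
            regions = classify_atac(regions, cfg.lfc_threshold, cfg.pseudocount)
        report.atac_labels = {r.interval.name: r.klass for r in regions}
        counts = {k: 0 for k in ("noDA", "loss", "gain")}
        for r in regions:
            counts[r.klass] += 1
        report.atac_class_counts = counts
        by_class = group_by_class(regions)
        for label, peaks in peaks_by_label.items():
            profs = coverage_vs_classes(peaks, by_class, query_label=label)
            for klass, prof in profs.items():
                long_profiles.append(prof)
                report.coverage_means[f"{label}.atac_{klass}"] = prof.mean()
    if cfg.histone_active is not None and cfg.histone_repressed is not None:
        active = read_bed(cfg.histone_active)
        repressed = read_bed(cfg.histone_repressed)
        for label, peaks in peaks_by_label.items():
            pa, pr = coverage_vs_histone(peaks, active, repressed, query_label=label)
            long_profiles.extend([pa, pr])
            report.coverage_means[f"{label}.histone_active"] = pa.mean()
            report.coverage_means[f"{label}.histone_repressed"] = pr.mean()
    if long_profiles:
        write_coverage_long(long_profiles, peaks_by_label, out / "coverage_long.tsv")

    report.provenance = {
        "config_sha256": cfg.sha256(),
        "package_version": __version__,
        "seed": str(cfg.seed),
    }
    report.to_json(out / "report.json")
    return report


def _export_fasta(regions: IntervalSet, fasta: pyfaidx.Fasta, path) -> None:
    """Region sequences as FASTA, for external motif-discovery tools."""
    with open(path, "w") as fh:
        for iv in regions:
            seq = str(fasta[iv.chrom][iv.start : iv.end])
            fh.write(f">{iv.name} {iv.chrom}:{iv.start}-{iv.end}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
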