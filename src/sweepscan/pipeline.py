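"""Pipeline orchestration: simulate -> filter -> stats -> scan -> structure.

A :class:`RunConfig` collects every knob of the analysis (input paths
or simulation parameters, filter thresholds, window geometry, scan
quantile, LD and PCA settings) in one flat, documented namespace that
round-trips through YAML.  :func:`run_pipeline` executes the requested
stages in dependency order, writes each module's tables under one
output directory and finishes with a machine-readable run manifest, so
two runs with the same config and seed produce identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .panel import GenotypePanel
from .popgen import (WindowSpec, genome_tajimas_d, ld_decay,
                     make_windows, windowed_tajimas_d)
from .simulate import SimParams, sample_and_write
from .structure import grm, nj_tree, pairwise_distance, pca_frame
from .sweep import (annotate_snps, annotation_tally, build_scan_table,
                    diagnostic_markers, genes_in_regions, joint_outliers,
                    markers_to_frame, merge_regions, regions_to_bed,
                    regions_to_frame)
from .variant_io import (filter_genotypes, filter_sites, read_gff3,
                         read_group_table, read_vcf, write_vcf)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "filter", "stats", "ldscan", "sweep",
              "structure", "annotate", "markers")


@dataclass
class RunConfig:
    """Flat configuration for a pipeline run.

    Either ``vcf``/``group_table`` (and optionally ``gff3``) point at
    real inputs, or ``simulate=True`` generates them with
    :class:`~sweepscan.simulate.SimParams` defaults overridden by
    ``sim_*`` keys.  ``seed`` is mandatory whenever a stochastic stage
    (simulation) runs.
    """

    out_dir: str = "sweepscan_out"
    seed: int | None = None
    # inputs
    vcf: str | None = None
    group_table: str | None = None
    gff3: str | None = None
    simulate: bool = False
    sim: dict = field(default_factory=dict)      # overrides for SimParams
    # filters
    min_dp: int = 3
    max_dp: int = 50
    min_mq: float = 20.0
    min_maf: float = 0.05
    max_miss: float = 0.1
    # windows / scan
    window_size: int = 20_000
    window_step: int = 10_000
    scan_q: float = 0.05
    min_snps: int = 10
    group_a: str | None = None      # ratio-numerator (reference) group
    # LD
    ld_max_dist: int = 5_000_000
    ld_bin_width: int = 50_000
    # PCA
    pca_k: int = 3
    chrom_lengths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.scan_q < 0.5):
            raise ValueError("scan_q must be in (0, 0.5)")
        if self.min_dp < 0 or self.max_dp < self.min_dp:
            raise ValueError("need 0 <= min_dp <= max_dp")
        if not (0 <= self.min_maf < 0.5 and 0 <= self.max_miss <= 1):
            raise ValueError("min_maf in [0, 0.5), max_miss in [0, 1]")
        self.window_spec()   # validates size/step

    def window_spec(self) -> WindowSpec:
        return WindowSpec(self.window_size, self.window_step)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load_inputs(config: RunConfig, out: Path, counts: dict) -> tuple[GenotypePanel, list, dict]:
    """Simulate if requested, then read VCF/groups/GFF3 into memory."""
    if config.simulate:
        if config.seed is None:
            raise ValueError("simulation requires a seed")
        params = SimParams(seed=config.seed, **config.sim)
        paths = sample_and_write(params, out / "sim", config.window_spec())
        config.vcf = str(paths["vcf"])
        config.group_table = str(paths["groups"])
        config.gff3 = str(paths["gff3"])
        if not config.chrom_lengths:
            config.chrom_lengths = {params.chrom: params.length}
        counts["simulated_sites"] = json.loads(
            paths["manifest"].read_text())["n_segregating"]
    if config.vcf is None or config.group_table is None:
        raise ValueError("need vcf and group_table (or simulate: true)")
    groups = read_group_table(config.group_table)
    panel = read_vcf(config.vcf, groups)
    genes = read_gff3(config.gff3) if config.gff3 else []
    counts["input_sites"] = panel.n_sites
    counts["samples"] = panel.n_samples
    counts["genes"] = len(genes)
    return panel, genes, groups


def _chrom_lengths(config: RunConfig, panel: GenotypePanel) -> dict[str, int]:
    if config.chrom_lengths:
        return {str(k): int(v) for k, v in config.chrom_lengths.items()}
    # fall back to the last observed position per chromosome
    out: dict[str, int] = {}
    for c, p in zip(panel.chrom, panel.pos):
        out[str(c)] = max(out.get(str(c), 0), int(p))
    return out


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = ALL_STAGES) -> Path:
    """Execute the requested stages; returns the output directory.

    Stages not requested are skipped, but every requested stage's
    prerequisites (reading inputs, filtering, windowed statistics) run
    implicitly since later stages consume their results in memory.
    """
    bad = set(stages) - set(ALL_STAGES)
    if bad:
        raise ValueError(f"unknown stages: {sorted(bad)}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict = {}

    panel, genes, groups = _load_inputs(config, out, counts)

    if "filter" in stages:
        panel = filter_genotypes(panel, config.min_dp, config.max_dp)
        panel, tally = filter_sites(panel, config.min_mq, config.min_maf,
                                    config.max_miss)
        tally.to_tsv(out / "filter_tally.tsv")
        write_vcf(panel, out / "filtered.vcf")
        counts["filtered_sites"] = panel.n_sites

    labels = panel.group_labels
    group_a = config.group_a or labels[0]
    group_b = [g for g in labels if g != group_a][0] if len(labels) == 2 else group_a

    windows = make_windows(_chrom_lengths(config, panel), config.window_spec())
    scan = None
    if {"stats", "sweep"} & set(stages):
        scan = build_scan_table(panel, windows, group_a, group_b)
        counts["windows"] = len(scan)

    if "stats" in stages:
        stats = scan.rename(columns={"pi_a": f"pi_{group_a}", "pi_b": f"pi_{group_b}"})
        stats.to_csv(out / "window_stats.tsv", sep="\t", index=False,
                     float_format="%.6g")
        taj = []
        for g in (group_a, group_b):
            t = windowed_tajimas_d(panel, g, windows)
            t.insert(0, "group", g)
            taj.append(t)
            res = genome_tajimas_d(panel, g)
            counts[f"tajima_d_{g}"] = None if np.isnan(res.D) else round(res.D, 4)
        import pandas as pd
        pd.concat(taj).to_csv(out / "tajima_d.tsv", sep="\t", index=False,
                              float_format="%.6g")

    if "ldscan" in stages:
        for g in (group_a, group_b):
            curve = ld_decay(panel, g, config.ld_max_dist, config.ld_bin_width,
                             min_maf=max(config.min_maf, 0.05))
            curve.to_frame().to_csv(out / f"ld_decay_{g}.tsv", sep="\t",
                                    index=False, float_format="%.6g")
            counts[f"ld_half_decay_bp_{g}"] = (
                None if np.isnan(curve.half_decay_distance)
                else curve.half_decay_distance)

    if "sweep" in stages:
        called = joint_outliers(scan, config.scan_q, config.min_snps,
                                group_a=group_a, group_b=group_b)
        called.to_csv(out / "scan_table.tsv", sep="\t", index=False,
                      float_format="%.6g")
        regions = genes_in_regions(merge_regions(called), genes)
        regions_to_frame(regions).to_csv(out / "sweep_regions.tsv", sep="\t",
                                         index=False, float_format="%.6g")
        regions_to_bed(regions, out / "sweep_regions.bed")
        counts["sweep_regions"] = len(regions)
        for direction in (f"{group_a}-selected", f"{group_b}-selected"):
            counts[f"regions_{direction}"] = sum(
                r.direction == direction for r in regions)

    if "structure" in stages:
        dist = pairwise_distance(panel)
        dist.to_frame().to_csv(out / "distance_matrix.tsv", sep="\t",
                               float_format="%.6g")
        (out / "nj_tree.nwk").write_text(nj_tree(dist) + "\n")
        g = grm(panel)
        pcs = pca_frame(g, min(config.pca_k, panel.n_samples))
        pcs.insert(0, "group", [groups[s] for s in pcs.index])
        pcs.to_csv(out / "pca.tsv", sep="\t", index_label="sample",
                   float_format="%.6g")
        evals = ",".join(f"{v:.6g}" for v in pcs.attrs["eigenvalues"])
        counts["pca_eigenvalues"] = evals

    if "annotate" in stages:
        ann = annotate_snps(panel, genes)
        ann.to_csv(out / "snp_annotation.tsv", sep="\t", index=False)
        annotation_tally(ann).to_csv(out / "snp_annotation_tally.tsv", sep="\t",
                                     index=False, float_format="%.4g")
        counts["annotated_snps"] = len(ann)

    if "markers" in stages:
        markers = diagnostic_markers(panel, max_miss=config.max_miss)
        markers_to_frame(markers, group_a, group_b).to_csv(
            out / "diagnostic_markers.tsv", sep="\t", index=False,
            float_format="%.6g")
        if markers:
            pos = {(m.chrom, m.pos) for m in markers}
            keep = np.array([(c, int(p)) in pos
                             for c, p in zip(panel.chrom, panel.pos)])
            write_vcf(panel.take_sites(keep), out / "diagnostic_markers.vcf")
        counts["diagnostic_markers"] = len(markers)

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "stages": list(stages),
        "counts": counts,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    logger.info("run_pipeline: wrote %s", out)
    return out
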