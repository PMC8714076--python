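"""End-to-end pipeline driver: file-based stage chaining with a run manifest.

Stages run in dependency order (confirm -> annotate / motif ->
call-degs -> integrate -> crosstalk). Inputs are never mutated; every
stage writes new files under the output directory. The manifest records
per-stage record counts, parameter values, output checksums and wall
times, so a rerun with identical configuration can be verified
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__, io as cio
from .annotation import DEFAULT_BIN_EDGES, annotate_peaks, conservation_profile, distance_histogram
from .crosstalk import build_grn, grn_to_dot, overlay_targets, shared_degs
from .de import DEGThresholds, call_degs, filter_expressed
from .integration import assign_targets, compare_density_classes, open_peaks, tad_density
from .intervals import GeneModel, ValidationError
from .motifs import build_matrix, hierarchical_cluster
from .replication import ReplicationConfig, confirm_replicated

logger = logging.getLogger("chromlink")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run; see the YAML example in docs."""

    chip_replicates: List[str]
    atac_bed: str
    genes_tsv: str
    tads_bed: str
    de_table_a: str
    de_table_b: str
    outdir: str
    conservation_bedgraph: Optional[str] = None
    genome_fasta: Optional[str] = None
    pwm_file: Optional[str] = None
    bias_tsv: Optional[str] = None
    stringent: float = 1e-5
    weak: float = 1e-2
    min_support: int = 1
    promoter_halfwidth: int = 2_500
    motif_window: int = 150
    motif_threshold: float = 1e-4
    fdr_max: float = 0.1
    fc_min: float = 1.2
    min_expression: float = 1.0
    min_samples: int = 3
    max_dist: float = 1_000_000
    pathway_a: str = "A"
    pathway_b: str = "B"

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        required = [*self.chip_replicates, self.atac_bed, self.genes_tsv, self.tads_bed, self.de_table_a, self.de_table_b]
        optional = [self.conservation_bedgraph, self.genome_fasta, self.pwm_file, self.bias_tsv]
        for p in required + [p for p in optional if p]:
            if not os.path.exists(p):
                raise ValidationError(f"input file missing: {p}")
        if len(self.chip_replicates) < 2:
            raise ValidationError("need at least two ChIP replicates")
        ReplicationConfig(self.stringent, self.weak, self.min_support)
        DEGThresholds(self.min_expression, self.min_samples, self.fdr_max, self.fc_min)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(cfg: PipelineConfig) -> str:
    return hashlib.sha256(json.dumps(dataclasses.asdict(cfg), sort_keys=True).encode()).hexdigest()[:16]


def _load_degs(path: str, thresholds: DEGThresholds, genes: Dict[str, GeneModel]) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    sample_cols = [c for c in table.columns if c.startswith("s") and c[1:].isdigit()]
    expr = table.set_index("gene_id")[sample_cols]
    chrom = table.set_index("gene_id")["chrom"]
    retained = filter_expressed(expr, chrom, thresholds)
    degs = call_degs(table, retained, thresholds)
    degs["chrom"] = degs["gene_id"].map(lambda g: genes[g].chrom if g in genes else None)
    degs["tss"] = degs["gene_id"].map(lambda g: genes[g].tss if g in genes else None)
    return degs


def run_pipeline(cfg: PipelineConfig) -> Dict:
    """Execute all stages; returns (and writes) the run manifest."""
    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)
    manifest: Dict = {
        "version": __version__,
        "config_hash": _config_hash(cfg),
        "parameters": dataclasses.asdict(cfg),
        "stages": {},
        "outputs": {},
    }

    def out(name: str) -> str:
        return os.path.join(cfg.outdir, name)

    def stage_done(name: str, t0: float, counts: Dict) -> None:
        manifest["stages"][name] = {"wall_seconds": round(time.time() - t0, 3), **counts}
        logger.info("stage %s done in %.2fs: %s", name, time.time() - t0, counts)

    # confirm
    t0 = time.time()
    replicates = [cio.read_narrowpeak(p, replicate_id=f"rep{i + 1}") for i, p in enumerate(cfg.chip_replicates)]
    rep_cfg = ReplicationConfig(cfg.stringent, cfg.weak, cfg.min_support)
    confirmed = confirm_replicated(replicates, rep_cfg)
    from .intervals import Peak

    cio.write_narrowpeak(
        [Peak(c.interval, c.summit, c.pvalue, name=f"support={c.support}") for c in confirmed],
        out("confirmed_peaks.narrowPeak"),
    )
    stage_done("confirm", t0, {"n_input_peaks": sum(map(len, replicates)), "n_confirmed": len(confirmed)})

    # annotate
    t0 = time.time()
    genes = cio.read_gene_models(cfg.genes_tsv, format="tsv")
    gene_map = {g.gene_id: g for g in genes}
    annotations = annotate_peaks(confirmed, genes, promoter_halfwidth=cfg.promoter_halfwidth)
    pd.DataFrame(
        {
            "chrom": [a.peak.chrom for a in annotations],
            "start": [a.peak.interval.start for a in annotations],
            "end": [a.peak.interval.end for a in annotations],
            "summit": [a.peak.summit for a in annotations],
            "nearest_gene": [a.nearest_gene for a in annotations],
            "tss_distance": [a.tss_distance for a in annotations],
            "category": [a.category for a in annotations],
        }
    ).to_csv(out("peak_annotations.tsv"), sep="\t", index=False)
    hist = distance_histogram(annotations)
    counts = {
        "n_promoter": sum(a.category == "promoter" for a in annotations),
        "n_intragenic": sum(a.category == "intragenic" for a in annotations),
        "n_intergenic": sum(a.category == "intergenic" for a in annotations),
        "distance_fractions": [round(float(x), 6) for x in hist],
    }
    stage_done("annotate", t0, counts)

    # conservation profile
    if cfg.conservation_bedgraph:
        t0 = time.time()
        track = cio.read_bedgraph(cfg.conservation_bedgraph)
        profile = conservation_profile(confirmed, track)
        pd.DataFrame(
            {"offset": profile.offsets, "mean_score": profile.mean_score, "n_peaks": profile.n_peaks}
        ).to_csv(out("conservation_profile.tsv"), sep="\t", index=False)
        stage_done("conservation", t0, {"center_mean": round(float(profile.mean_score[len(profile.mean_score) // 2]), 6)})

    # motif matrix
    if cfg.genome_fasta and cfg.pwm_file:
        t0 = time.time()
        import pyfaidx

        fasta = pyfaidx.Fasta(cfg.genome_fasta)
        regions = {}
        for i, c in enumerate(confirmed):
            lo = max(0, c.summit - cfg.motif_window)
            hi = c.summit + cfg.motif_window
            regions[f"{c.chrom}:{c.interval.start}-{c.interval.end}"] = str(fasta[c.chrom][lo:hi])
        pwms = cio.read_pwms(cfg.pwm_file)
        matrix = build_matrix(regions, pwms, threshold=cfg.motif_threshold)
        matrix.rename_axis("region").to_csv(out("motif_matrix.tsv"), sep="\t", float_format="%.6g")
        if len(matrix) >= 2:
            Z, order = hierarchical_cluster(matrix)
            np.savetxt(out("motif_linkage.tsv"), Z, delimiter="\t", fmt="%.6g")
        stage_done("motif", t0, {"n_regions": len(regions), "n_motifs": len(pwms), "n_hit_cells": int((matrix.to_numpy() > 0).sum())})

    # call-degs
    t0 = time.time()
    thresholds = DEGThresholds(cfg.min_expression, cfg.min_samples, cfg.fdr_max, cfg.fc_min)
    degs_a = _load_degs(cfg.de_table_a, thresholds, gene_map)
    degs_b = _load_degs(cfg.de_table_b, thresholds, gene_map)
    degs_a.to_csv(out("degs_a.tsv"), sep="\t", index=False, float_format="%.6g")
    degs_b.to_csv(out("degs_b.tsv"), sep="\t", index=False, float_format="%.6g")
    stage_done(
        "call_degs",
        t0,
        {
            "a_up": int((degs_a["direction"] == "up").sum()),
            "a_down": int((degs_a["direction"] == "down").sum()),
            "b_up": int((degs_b["direction"] == "up").sum()),
            "b_down": int((degs_b["direction"] == "down").sum()),
        },
    )

    # integrate
    t0 = time.time()
    atac = cio.read_bed(cfg.atac_bed)
    opened = open_peaks(confirmed, atac)
    targets = assign_targets(opened, degs_a, max_dist=cfg.max_dist)
    pd.DataFrame(
        {
            "gene_id": [t.gene_id for t in targets],
            "direction": [t.direction for t in targets],
            "n_peaks": [t.n_peaks for t in targets],
            "min_abs_distance": [t.min_abs_distance for t in targets],
        }
    ).to_csv(out("targets.tsv"), sep="\t", index=False)
    tads = cio.read_tads(cfg.tads_bed)
    expressed = degs_a["gene_id"].tolist()
    density, outside = tad_density(confirmed, tads, [gene_map[g] for g in expressed if g in gene_map])
    labels = degs_a.set_index("gene_id")["direction"].reindex(density.index)
    stats_block: Dict = {}
    class_sizes = labels.value_counts()
    if all(class_sizes.get(k, 0) >= 2 for k in ("up", "down", "unchanged")):
        result = compare_density_classes(density, labels)
        stats_block = {
            "p_up_vs_unchanged": result.p_up_vs_unchanged,
            "p_down_vs_unchanged": result.p_down_vs_unchanged,
            "p_up_vs_down": result.p_up_vs_down,
        }
    density.rename_axis("gene_id").rename("density").to_csv(out("tad_density.tsv"), sep="\t", float_format="%.6g")
    with open(out("integration_stats.json"), "w") as fh:
        json.dump(stats_block, fh, indent=1)
    stage_done(
        "integrate",
        t0,
        {"n_open_peaks": len(opened), "n_targets": len(targets), "n_genes_outside_tads": len(outside), **stats_block},
    )

    # crosstalk
    t0 = time.time()
    shared = shared_degs(degs_a, degs_b)
    shared = overlay_targets(shared, [t.gene_id for t in targets])
    shared.to_csv(out("shared_degs.tsv"), sep="\t", index=False, float_format="%.6g")
    if cfg.bias_tsv:
        bias = pd.read_csv(cfg.bias_tsv, sep="\t").set_index("gene_id")["category"]
    else:
        bias = pd.Series(dtype=object)
    edges = build_grn(shared, bias, pathway_a=cfg.pathway_a, pathway_b=cfg.pathway_b)
    edges.to_csv(out("grn_edges.tsv"), sep="\t", index=False)
    with open(out("grn.dot"), "w") as fh:
        fh.write(grn_to_dot(edges) + "\n")
    stage_done(
        "crosstalk",
        t0,
        {
            "n_shared": len(shared),
            "n_concordant": int((shared["concordance"] == "concordant").sum()),
            "n_discordant": int((shared["concordance"] == "discordant").sum()),
            "n_shared_targets": int(shared["is_target_a"].sum()),
            "n_edges": len(edges),
        },
    )

    for name in sorted(os.listdir(cfg.outdir)):
        p = os.path.join(cfg.outdir, name)
        if os.path.isfile(p) and name != "manifest.json":
            manifest["outputs"][name] = _sha256(p)
    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
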