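"""End-to-end orchestration: scan -> effector filter -> cluster -> phylo.

A single validated config (YAML-loadable, unknown keys rejected) drives all
stages; every stage persists its table before the next runs, so a failure
still leaves partial results plus an error record naming the failed stage.
The report carries a provenance block (config hash, version, seeds, stage
funnel counts) so that "which thresholds produced these counts" is always
answerable, and reruns with identical config + inputs are bit-identical
except for timestamps.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .clusters import (
    T3SSCluster,
    assemble_clusters,
    default_panel,
    find_components,
    load_panel,
)
from .effectors import EffectorThresholds, candidates_to_frame, run_effector_screen
from .genome import AnnotatedGenome, read_genome
from .motifs import PATTERNS, screen_genome, write_hits_bed, write_hits_tsv
from .phylo import MSA, PhyloTree, bootstrap_support, write_newick, write_support_json

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "StageError", "run_pipeline"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MotifStage(_Strict):
    pattern: str = "hrp_box_screen"
    min_dist: int = Field(30, ge=0)
    max_dist: int = Field(300, ge=0)
    max_mismatches_per_element: int = Field(0, ge=0)
    window: Optional[int] = None


class EffectorStage(_Strict):
    window: int = Field(50, ge=12)
    min_ser_frac: float = Field(0.10, ge=0.0, le=1.0)
    min_polar_frac: float = Field(0.40, ge=0.0, le=1.0)
    acidic_rule: Literal["at_most_one", "none", "at_least_one"] = "at_most_one"
    polar_set: str = "STNQCYGH"
    aliphatic_set: str = "ILVAP"

    def to_thresholds(self) -> EffectorThresholds:
        return EffectorThresholds(
            window=self.window,
            min_ser_frac=self.min_ser_frac,
            min_polar_frac=self.min_polar_frac,
            acidic_rule=self.acidic_rule,
            polar_set=frozenset(self.polar_set),
            aliphatic_set=frozenset(self.aliphatic_set),
        )


class ClusterStage(_Strict):
    panel: Optional[str] = None  # path to a panel FASTA; None -> packaged panel
    min_identity: float = Field(30.0, ge=0.0, le=100.0)
    min_coverage: float = Field(0.5, gt=0.0, le=1.0)
    matrix: str = "BLOSUM62"
    gap_open: float = Field(11.0, ge=0.0)
    gap_extend: float = Field(1.0, ge=0.0)
    max_gap: int = Field(5000, ge=0)


class PhyloStage(_Strict):
    alignment: Optional[str] = None  # aligned multi-FASTA path
    model: Literal["k80", "jc_protein"] = "k80"
    deletion: Literal["pairwise", "complete"] = "pairwise"
    n_replicates: int = Field(1000, ge=1)
    seed: int = 0


class RunConfig(_Strict):
    genome: Optional[str] = None
    genome_format: Literal["genbank", "fasta+gff3"] = "genbank"
    gff3: Optional[str] = None
    outdir: str = "t3mine_out"
    stages: list[Literal["scan", "effectors", "clusters", "phylo"]] = Field(
        default_factory=lambda: ["scan", "effectors", "clusters"]
    )
    motif: MotifStage = Field(default_factory=MotifStage)
    effector: EffectorStage = Field(default_factory=EffectorStage)
    cluster: ClusterStage = Field(default_factory=ClusterStage)
    phylo: PhyloStage = Field(default_factory=PhyloStage)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class StageError:
    stage: str
    message: str


@dataclass
class RunReport:
    motif_table: pd.DataFrame | None = None
    candidates: list | None = None
    feature_table: pd.DataFrame | None = None
    clusters: list[T3SSCluster] | None = None
    tree: PhyloTree | None = None
    counts: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    error: StageError | None = None

    def summary(self) -> dict:
        out = {"provenance": self.provenance, "counts": self.counts}
        if self.error:
            out["error"] = {"stage": self.error.stage, "message": self.error.message}
        return out


def run_pipeline(
    config: RunConfig,
    genome: AnnotatedGenome | None = None,
    alignment: MSA | None = None,
) -> RunReport:
    """Execute the configured stages in order, persisting results per stage.

    ``genome``/``alignment`` may be passed directly (e.g. fresh from the
    simulator) instead of via config paths.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        provenance={
            "version": __version__,
            "config_hash": config.config_hash(),
            "config": config.model_dump(),
            "started": datetime.now(timezone.utc).isoformat(),
        }
    )
    stage = "genome_io"
    try:
        if genome is None and config.genome:
            genome = read_genome(
                config.genome, config.genome_format.replace("fasta+gff3", "fasta+gff3"),
                gff3=config.gff3,
            )
        if genome is None and set(config.stages) & {"scan", "effectors", "clusters"}:
            raise ValueError("no genome given (config.genome or genome=)")

        if "scan" in config.stages:
            stage = "motif_scan"
            pattern = PATTERNS[config.motif.pattern]
            logger.info("scan: pattern=%s dist=[%d,%d]", pattern.name,
                        config.motif.min_dist, config.motif.max_dist)
            table = screen_genome(
                genome, pattern, config.motif.min_dist, config.motif.max_dist,
                window=config.motif.window,
                max_mismatches_per_element=config.motif.max_mismatches_per_element,
            )
            report.motif_table = table
            report.counts["hrp_box_genes"] = int(len(table))
            write_hits_tsv(table, outdir / "hrp_box_genes.tsv")
            if len(table):
                write_hits_bed(table, outdir / "hrp_box_genes.bed")

        if "effectors" in config.stages:
            stage = "effector_filter"
            if report.motif_table is None:
                raise ValueError("effector stage requires the scan stage")
            thresholds = config.effector.to_thresholds()
            candidates, feats = run_effector_screen(genome, report.motif_table, thresholds)
            report.candidates, report.feature_table = candidates, feats
            n_pos = sum(c.is_putative_effector for c in candidates)
            report.counts["putative_effectors"] = int(n_pos)
            report.counts["unevaluable_genes"] = sum(
                1 for c in candidates if c.unevaluable_reason
            )
            candidates_to_frame(candidates).to_csv(
                outdir / "effector_candidates.tsv", sep="\t", index=False
            )
            feats.to_csv(outdir / "nterm_features.tsv", sep="\t", index=False)

        if "clusters" in config.stages:
            stage = "cluster_finder"
            panel = load_panel(config.cluster.panel) if config.cluster.panel else default_panel()
            hits = find_components(
                genome, panel,
                min_identity=config.cluster.min_identity,
                min_coverage=config.cluster.min_coverage,
                matrix=config.cluster.matrix,
                gap_open=config.cluster.gap_open,
                gap_extend=config.cluster.gap_extend,
            )
            clusters = assemble_clusters(hits, genome, config.cluster.max_gap)
            report.clusters = clusters
            report.counts["component_hits"] = len(hits)
            report.counts["t3ss_clusters"] = len(clusters)
            _write_cluster_reports(clusters, genome, outdir)

        if "phylo" in config.stages:
            stage = "phylo"
            if alignment is None:
                if not config.phylo.alignment:
                    raise ValueError("phylo stage requires an alignment path or alignment=")
                alignment = MSA.from_fasta(config.phylo.alignment)
            tree = bootstrap_support(
                alignment,
                n_replicates=config.phylo.n_replicates,
                distance=config.phylo.model,
                seed=config.phylo.seed,
                deletion=config.phylo.deletion,
            )
            report.tree = tree
            report.counts["phylo_taxa"] = alignment.n_taxa
            write_newick(tree, outdir / "tree.nwk")
            write_support_json(tree, outdir / "tree_support.json")
    except Exception as exc:  # per-stage error record, partial results kept
        report.error = StageError(stage, str(exc))
        logger.error("stage %s failed: %s", stage, exc)

    report.provenance["finished"] = datetime.now(timezone.utc).isoformat()
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report.summary(), fh, indent=2, default=str)
    return report


def _write_cluster_reports(clusters, genome, outdir: Path) -> None:
    rows = []
    for k, c in enumerate(clusters, 1):
        for h in c.member_hits:
            f = genome.get_cds(h.gene_id)
            rows.append(
                {
                    "cluster": k, "contig_id": c.contig_id, "gene_id": h.gene_id,
                    "component": h.component_name, "role": h.role,
                    "start": f.start, "end": f.end, "strand": f.strand,
                    "score": h.alignment_score,
                    "percent_identity": round(h.percent_identity, 2),
                    "coverage": round(h.query_coverage, 3),
                    "span_bp": c.span_bp,
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "t3ss_clusters.tsv", sep="\t", index=False)
    with open(outdir / "t3ss_clusters.json", "w") as fh:
        json.dump(
            [
                {
                    "contig_id": c.contig_id,
                    "start": c.start,
                    "end": c.end,
                    "span_bp": c.span_bp,
                    "members": [
                        {
                            "gene_id": h.gene_id,
                            "component": h.component_name,
                            "role": h.role,
                            "percent_identity": round(h.percent_identity, 2),
                        }
                        for h in c.member_hits
                    ],
                    "present_roles": list(c.present_roles),
                    "missing_components": list(c.missing_components),
                }
                for c in clusters
            ],
            fh,
            indent=2,
        )
    # GFF3 track of cluster members for genome-browser use
    with open(outdir / "t3ss_clusters.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for k, c in enumerate(clusters, 1):
            for h in c.member_hits:
                f = genome.get_cds(h.gene_id)
                fh.write(
                    f"{c.contig_id}\tt3mine\tCDS\t{f.start}\t{f.end}\t"
                    f"{h.alignment_score:.0f}\t{f.strand}\t.\t"
                    f"ID={h.gene_id};component={h.component_name};cluster={k}\n"
                )
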