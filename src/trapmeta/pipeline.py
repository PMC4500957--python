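"""End-to-end driver: simulate -> partition -> profile -> enrich ->
contigs -> dge, with stage-level logging and a machine-readable metrics
report.

Every numeric in the metrics JSON is produced by exactly one operation of
the stage modules; the report layer only collects (and rounds percents
where a table convention demands it).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import contigs as contig_mod
from . import dge as dge_mod
from . import simulate as sim
from .design import trap_leaf_pairs
from .enrichment import (ClassifierThresholds, bray_curtis,
                         classify_active_microbiome, phenotype_profile, upgma)
from .partition import CompositionSummary, partition_library
from .phylotypes import rarefaction_curve, summarize_phylotypes
from .alignment import ReferenceIndex

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline thresholds at their published defaults, plus the seed."""

    seed: int = 0
    outdir: str = "trapmeta_run"
    # read mapping
    strict_identity: float = 0.97
    fallback_identity: float = 0.80
    min_length_fraction: float = 0.90
    quality_limit: float = 0.05
    min_read_length: int = 80
    # classifier
    min_abundance_pct: float = 0.1
    min_occurrence: int = 2
    min_fold: float = 2.0
    # contigs
    evalue_cut: float = 1e-9
    min_bitscore: float = 50.0
    annotation_window: tuple = (1500, 8000)
    # dge
    p_cut: float = 0.05
    log2_cut: float = 0.0
    offset: float = 1.0
    # stage toggles
    skip_contigs: bool = False
    skip_reads: bool = False
    simulation: sim.SimulationConfig = field(default_factory=sim.SimulationConfig)

    def __post_init__(self):
        if isinstance(self.simulation, dict):
            self.simulation = sim.SimulationConfig(**self.simulation)
        self.simulation.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["annotation_window"] = list(self.annotation_window)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else round(f, 10)
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on a synthetic fixture and write the report bundle.

    Outputs under ``config.outdir``: the serialized configuration, the
    fixture tables (taxonomy, metadata, abundance), the composition
    summary, enrichment table, dendrogram, phenotype profile, contig
    cascade report, annotation tallies, GO enrichment, DEG table, and
    ``metrics.json`` summarizing every stage. Returns the metrics dict.
    A stage failure aborts with the stage name; outputs of completed
    stages are retained.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    metrics: dict = {"seed": config.seed}
    stage = "simulate"
    try:
        # --- simulate ---------------------------------------------------
        scfg = config.simulation
        taxonomy = sim.make_taxonomy(scfg)
        taxonomy.write_tsv(out / "taxonomy.tsv")
        table, truth = sim.simulate_community_counts(scfg, taxonomy)
        table.metadata.to_csv(out / "metadata.tsv", sep="\t")
        table.write_tsv(out / "abundance.tsv")
        table.to_long().to_csv(out / "abundance_long.tsv", sep="\t", index=False)
        logger.info("simulate: %d genera x %d samples", *table.counts.shape)

        # --- partition (read-level, optional) --------------------------
        stage = "partition"
        if not config.skip_reads:
            references = sim.make_references(scfg, taxonomy)
            reads_by_sample, read_truth = sim.simulate_reads(scfg, references)
            rrna_index = ReferenceIndex(references["rRNA"])
            host_index = ReferenceIndex(references["host"])
            results = []
            correct = 0
            n_reads = 0
            for s, reads in reads_by_sample.items():
                res = partition_library(
                    reads, rrna_index, host_index, sample_id=s,
                    strict_identity=config.strict_identity,
                    fallback_identity=config.fallback_identity,
                    min_length_fraction=config.min_length_fraction,
                    quality_limit=config.quality_limit,
                    min_len=config.min_read_length)
                results.append(res)
                for bin_name, bin_reads in res.bins.items():
                    for r in bin_reads:
                        n_reads += 1
                        if read_truth.read_origin[r.read_id][1] == bin_name:
                            correct += 1
            summary = CompositionSummary.from_partitions(results)
            summary.write_tsv(out / "composition_summary.tsv")
            metrics["partition"] = {
                "n_reads": n_reads,
                "bin_accuracy": correct / n_reads if n_reads else None,
                "composition": summary.frame.to_dict(orient="records"),
            }
            # profile the rRNA bins of the simulated reads
            stage = "profile"
            import pandas as pd
            assignments = pd.concat(
                [r.rrna_assignments for r in results], ignore_index=True)
            read_table = summarize_phylotypes(assignments, taxonomy,
                                              table.metadata)
            read_table.write_tsv(out / "read_level_abundance.tsv")
            metrics["profile"] = {
                "n_genera_read_level": int(len(read_table.counts)),
            }

        # --- profile/rarefaction on the count fixture -------------------
        stage = "profile"
        totals = table.counts.sum(axis=1)
        depths = [1, int(totals.sum() // 100), int(totals.sum() // 10)]
        curve = rarefaction_curve(totals.values, depths, reps=50,
                                  seed=config.seed)
        curve.to_csv(out / "rarefaction.tsv", sep="\t")
        metrics.setdefault("profile", {})["richness"] = int((totals > 0).sum())

        # --- enrich ------------------------------------------------------
        stage = "enrich"
        thresholds = ClassifierThresholds(
            min_abundance_pct=config.min_abundance_pct,
            min_occurrence=config.min_occurrence,
            min_fold=config.min_fold)
        records = classify_active_microbiome(table, thresholds)
        records.to_csv(out / "enrichment.tsv", sep="\t")
        called = set(records.index[records["active"]])
        planted = truth.active_set
        tp = len(called & planted)
        precision = tp / len(called) if called else 1.0
        recall = tp / len(planted) if planted else 1.0
        census = records[records["active"]].groupby("category").size()
        newick = upgma(bray_curtis(table))
        (out / "dendrogram.nwk").write_text(newick + "\n")
        phen = sim.make_phenotypes(scfg, taxonomy)
        phen.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
        bacteria = [g for g in table.counts.index
                    if table.categories[g] == "Bacteria"]
        trap_cols = [s for s in table.samples
                     if table.metadata.at[s, "organ"] == "trap"]
        abund = table.counts[trap_cols].sum(axis=1).astype(float)
        profile_tbl = phenotype_profile(
            {"whole_trap": bacteria,
             "active": sorted(set(bacteria) & called)},
            abund, phen)
        profile_tbl.to_csv(out / "phenotype_profile.tsv", sep="\t", index=False)
        metrics["enrich"] = {
            "n_active": int(len(called)),
            "active_per_category": {k: int(v) for k, v in census.items()},
            "precision": precision,
            "recall": recall,
            "dendrogram": newick,
        }

        # --- contigs ------------------------------------------------------
        if not config.skip_contigs:
            stage = "contigs"
            bundle = sim.make_contigs_and_hits(scfg, taxonomy)
            result = contig_mod.filter_cascade(
                bundle.trap_contigs, bundle.host_transcripts,
                bundle.rrna_refs, bundle.leaf_contigs,
                evalue_cut=config.evalue_cut)
            result.removed.to_csv(out / "cascade_removed.tsv", sep="\t",
                                  index=False)
            survivors = sorted(c.contig_id for c in result.survivors)
            window = contig_mod.select_annotation_window(
                result.survivors, *config.annotation_window)
            assigned = {}
            for c in window:
                hits = bundle.protein_hits[
                    bundle.protein_hits["qseqid"] == c.contig_id]
                node = contig_mod.assign_taxon(hits, taxonomy,
                                               min_bitscore=config.min_bitscore)
                assigned[c.contig_id] = contig_mod.category_of_assignment(
                    taxonomy, node)
            tallies = contig_mod.tally_functions(bundle.annotations)
            sub = bundle.annotations[
                bundle.annotations["ec"].str.startswith("3")]
            go = contig_mod.go_enrichment(sub, bundle.annotations,
                                          bundle.ontology)
            go.to_csv(out / "go_enrichment.tsv", sep="\t", index=False)
            metrics["contigs"] = {
                "stage_counts": {k: int(v) for k, v in
                                 result.stage_counts().items()},
                "n_survivors": len(survivors),
                "survivors_match_planted":
                    survivors == bundle.truth.planted_keepers,
                "n_annotation_window": len(window),
                "n_taxon_assigned": sum(
                    1 for v in assigned.values() if v != "Unassigned"),
                "tallies": tallies,
                "n_go_significant": int(go["significant"].sum())
                if len(go) else 0,
            }

        # --- dge ---------------------------------------------------------
        stage = "dge"
        matrix, expr_truth = sim.simulate_expression(scfg)
        dge_mod.write_count_matrix(matrix, out / "host_counts.tsv")
        pairs = trap_leaf_pairs(table.metadata)
        deg_records, deg_summary = dge_mod.call_degs(
            matrix, pairs, p_cut=config.p_cut, log2_cut=config.log2_cut,
            offset=config.offset)
        deg_records.to_csv(out / "deg_table.tsv", sep="\t")
        strong, strong_summary = dge_mod.call_degs(
            matrix, pairs, p_cut=config.p_cut, log2_cut=1.0,
            offset=config.offset)
        called_deg = set(strong.index[strong["deg"]])
        planted_deg = set(expr_truth.planted_deg_genes)
        tp = len(called_deg & planted_deg)
        metrics["dge"] = {
            **deg_summary,
            "n_deg_twofold": int(strong["deg"].sum()),
            "deg_precision": tp / len(called_deg) if called_deg else 1.0,
            "deg_recall": tp / len(planted_deg) if planted_deg else 1.0,
        }
    except Exception as exc:
        logger.error("pipeline failed at stage %s", stage)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    metrics_clean = _jsonable(metrics)
    with open(out / "metrics.json", "w") as fh:
        json.dump(metrics_clean, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return metrics_clean
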