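"""End-to-end orchestration of the screening chain.

Stages, in order: ADME compound filter -> compound-target mapping ->
multi-source disease union and drug-disease intersection -> scored-PPI
construction and median-centrality core extraction -> over-representation
analysis -> median-split log-rank prognostic screen (with a stricter
refinement cut) -> docking-table triage -> bipartite regulatory-network
export.  Every intermediate table is written to the output directory and a
JSON manifest records input digests, the parameters actually used, and the
record count at each stage.

The pipeline proper is deterministic: all randomness lives in
:mod:`herbnet.synthetic_data`.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import yaml

from . import compound_screen as cs
from . import docking_results as dr
from . import enrichment as en
from . import geneset_ops as gs
from . import ppi_topology as ppi
from . import survival_screen as ss

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "export_regulatory_network"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the partial manifest."""

    def __init__(self, stage: str, manifest: dict, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest


@dataclass(frozen=True)
class PipelineConfig:
    """Flat, file-serializable pipeline configuration.

    Defaults mirror the conventional screen: OB >= 30%, DL >= 0.18, PPI score
    cut 0.9, one six-metric median-screening round, enrichment thresholds
    p <= 0.05 and q <= 0.05 with top-30 reporting, survival screen at
    p < 0.05 refined at p < 0.01.
    """

    compound_tables: dict[str, str] = field(default_factory=dict)  # herb -> path
    target_map: str = ""
    disease_sources: tuple[str, ...] = ()
    ppi_edges: str = ""
    alias_table: str | None = None
    docking_table: str | None = None
    annotations: str | None = None
    clinical: str | None = None
    expression: str | None = None
    outdir: str = "herbnet_out"
    ob_min: float = 30.0
    dl_min: float = 0.18
    min_score: float = 0.9
    metrics: tuple[str, ...] = ppi.METRICS
    rounds: int | str = 1
    p_max: float = 0.05
    q_max: float = 0.05
    top_n: int = 30
    annotation_category: str = "PATHWAY"
    alpha: float = 0.05
    alpha_refine: float = 0.01

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "disease_sources" in raw:
            raw["disease_sources"] = tuple(raw["disease_sources"])
        if "metrics" in raw:
            raw["metrics"] = tuple(raw["metrics"])
        return cls(**raw)

    def validate(self) -> None:
        paths = [*self.compound_tables.values(), self.target_map, self.ppi_edges,
                 *self.disease_sources]
        for opt in (self.alias_table, self.docking_table, self.annotations,
                    self.clinical, self.expression):
            if opt:
                paths.append(opt)
        missing = [p for p in paths if p and not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")
        if not 0 <= self.min_score <= 1:
            raise ValueError("min_score must lie in [0, 1]")
        for name, v in (("p_max", self.p_max), ("q_max", self.q_max),
                        ("alpha", self.alpha), ("alpha_refine", self.alpha_refine)):
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def export_regulatory_network(
    compounds: list[cs.Compound],
    target_map: gs.TargetMap,
    genes: set[str] | frozenset[str],
) -> nx.Graph:
    """Bipartite compound-gene regulatory network.

    Node attributes: ``kind`` (compound/gene), ``herb`` membership for
    compounds (a single herb name, or ``both`` for ingredients shared by two
    herbs), and ``degree``.  Only edges to ``genes`` and from the supplied
    compounds are kept.
    """
    herb_of: dict[str, str] = {}
    name_of: dict[str, str] = {}
    for c in compounds:
        name_of[c.mol_id] = c.name
        prev = herb_of.get(c.mol_id)
        herb_of[c.mol_id] = c.herb if prev in (None, c.herb) else "both"
    g = nx.Graph()
    for mol, gene in sorted(target_map.edges):
        if mol in herb_of and gene in genes:
            g.add_node(mol, kind="compound", herb=herb_of[mol], name=name_of[mol])
            g.add_node(gene, kind="gene")
            g.add_edge(mol, gene)
    for v in g.nodes:
        g.nodes[v]["degree"] = g.degree(v)
    return g


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; returns the manifest (also written to disk).

    Optional stages (enrichment, survival, docking) are skipped when their
    inputs are not configured.  Any stage failure raises
    :class:`PipelineError` carrying the partial manifest.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = asdict(config)
    manifest: dict = {"parameters": params, "inputs": {}, "counts": {}, "stages_completed": []}
    counts = manifest["counts"]
    for label, p in [*config.compound_tables.items(), ("target_map", config.target_map),
                     *[(f"disease_{i}", s) for i, s in enumerate(config.disease_sources)]]:
        if p:
            manifest["inputs"][str(label)] = _sha256(p)
    logger.info("pipeline parameters: %s", json.dumps(params, default=str, sort_keys=True))

    stage = "compounds"
    try:
        compounds: list[cs.Compound] = []
        for herb, path in config.compound_tables.items():
            compounds.extend(cs.read_compound_table(path, herb=herb))
        active = cs.filter_compounds(compounds, cs.AdmeThresholds(config.ob_min, config.dl_min))
        cs.write_compound_table(active, outdir / "active_compounds.tsv")
        counts["compounds_in"] = len(compounds)
        counts["compounds_active"] = len(active)
        manifest["stages_completed"].append(stage)

        stage = "targets"
        tmap = gs.TargetMap.read(config.target_map)
        active_ids = {c.mol_id for c in active}
        tmap = gs.TargetMap(frozenset(e for e in tmap.edges if e[0] in active_ids))
        drug_targets = tmap.all_targets()
        counts["drug_targets"] = len(drug_targets)
        manifest["stages_completed"].append(stage)

        stage = "intersect"
        alias = gs.read_alias_table(config.alias_table) if config.alias_table else None
        sources = [gs.read_gene_list(p, alias_map=alias) for p in config.disease_sources]
        disease, per_source, _ = gs.union_sources(sources, label="disease")
        counts["disease_sources"] = per_source
        counts["disease_union"] = len(disease)
        intersection = gs.intersect_drug_disease(drug_targets, disease)
        counts["intersection"] = len(intersection)
        (outdir / "intersection_genes.txt").write_text(
            "\n".join(intersection.sorted()) + "\n", encoding="utf-8")
        if 2 <= len(sources) <= 5:
            gs.write_venn_counts(gs.venn_counts(sources), [s.label for s in sources],
                                 outdir / "disease_venn_counts.csv")
        manifest["stages_completed"].append(stage)

        stage = "ppi"
        edges = ppi.read_scored_edges(config.ppi_edges)
        edges = [e for e in edges if e.a in intersection.symbols and e.b in intersection.symbols]
        net = ppi.build_network(edges, min_score=config.min_score)
        counts["ppi_nodes"] = net.number_of_nodes()
        counts["ppi_edges"] = net.number_of_edges()
        if net.number_of_nodes() == 0:
            raise ValueError("no PPI edges survive the score threshold within the intersection")
        table = ppi.compute_centralities(net, config.metrics)
        ppi.write_centrality_table(table, outdir / "centralities.csv")
        screen = ppi.screen_core(net, ppi.ScreenConfig(tuple(config.metrics), config.rounds))
        core = gs.GeneSet("core", frozenset(screen.retained))
        counts["core_targets"] = len(core)
        counts["core_screen_terminal"] = screen.terminal
        (outdir / "core_targets.txt").write_text("\n".join(core.sorted()) + "\n", encoding="utf-8")
        ppi.export_graphml(net, outdir / "ppi_network.graphml")
        ppi.export_sif(net, outdir / "ppi_network.sif")
        manifest["stages_completed"].append(stage)

        stage = "enrich"
        if config.annotations:
            collection = en.read_gmt(config.annotations, category=config.annotation_category)
            results = en.enrich(intersection, collection, p_max=config.p_max,
                                q_max=config.q_max, top_n=config.top_n)
            en.results_to_frame(results).to_csv(outdir / "enrichment.csv", index=False)
            counts["enriched_terms"] = len(results)
            manifest["stages_completed"].append(stage)

        stage = "survival"
        if config.clinical and config.expression:
            cohort = ss.SurvivalCohort.read(config.clinical, config.expression)
            out = ss.survival_screen(cohort, intersection, alpha=config.alpha)
            out.table.to_csv(outdir / "survival_screen.csv", index=False)
            prognostic = {r.gene for r in out.passing}
            prog_core = sorted(prognostic & core.symbols)
            refined = sorted(r.gene for r in out.passing
                             if r.p < config.alpha_refine and r.gene in core.symbols)
            counts["patients"] = cohort.n_patients
            counts["prognostic_genes"] = len(prognostic)
            counts["prognostic_core_genes"] = len(prog_core)
            counts["refined_core_genes"] = len(refined)
            (outdir / "prognostic_core_genes.txt").write_text(
                "\n".join(prog_core) + "\n", encoding="utf-8")
            (outdir / "refined_core_genes.txt").write_text(
                "\n".join(refined) + "\n", encoding="utf-8")
            manifest["stages_completed"].append(stage)

        stage = "docking"
        if config.docking_table:
            records = dr.read_docking_table(config.docking_table)
            ranked, best = dr.rank_docking(records, per_target=True)
            dr.write_docking_table(ranked, outdir / "docking_ranked.csv")
            counts["docking_records"] = len(ranked)
            if ranked:
                counts["docking_best_affinity"] = ranked[0].affinity
                counts["docking_per_target_best"] = {t: r.affinity for t, r in sorted(best.items())}
            manifest["stages_completed"].append(stage)

        stage = "regulatory_network"
        regnet = export_regulatory_network(active, tmap, core.symbols)
        ppi.export_graphml(regnet, outdir / "regulatory_network.graphml")
        ppi.export_sif(regnet, outdir / "regulatory_network.sif", relation="ct")
        counts["regulatory_nodes"] = regnet.number_of_nodes()
        counts["regulatory_edges"] = regnet.number_of_edges()
        manifest["stages_completed"].append(stage)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n", encoding="utf-8")
        raise PipelineError(stage, manifest, exc) from exc

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n", encoding="utf-8")
    return manifest
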