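"""Seeded synthetic-data generators with planted ground truth.

Every pipeline stage normally consumes a database export (compound ADME
tables, compound-target maps, disease gene lists, a scored PPI edge list,
GMT annotation collections, a clinical survival cohort).  This module
fabricates each of those inputs with the statistical structure the stage
assumes — and with planted signal (a dense PPI core, enriched terms,
hazard-ratio genes, a drug-disease gene overlap) returned as ground truth so
recovery can be measured.

All generators are pure functions of (config, seed): one root seed feeds
independent per-generator substreams (fixed ``spawn_key`` per generator), so
adding a generator never perturbs the outputs of existing ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .compound_screen import Compound, write_compound_table
from .enrichment import AnnotationCollection, write_gmt
from .geneset_ops import GeneSet, TargetMap
from .ppi_topology import ScoredEdge
from .survival_screen import SurvivalCohort

__all__ = [
    "SynthConfig",
    "gen_compounds",
    "gen_drug_disease",
    "gen_ppi",
    "gen_annotations",
    "gen_survival",
    "generate_bundle",
]

# Fixed substream keys: appending new generators must not shift existing ones.
_STREAMS = {"compounds": 0, "targets": 1, "disease": 2, "ppi": 3, "annotations": 4, "survival": 5}


def _rng(config: "SynthConfig", stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(_STREAMS[stream],)))


@dataclass(frozen=True)
class SynthConfig:
    """All knobs for the synthetic inputs.

    OB is drawn from a normal truncated to [0, 100] (percent scale) and DL
    from a Beta distribution, roughly matching the location and spread of
    curated herbal-compound ADME tables.  The PPI is a dense Erdos-Renyi core
    (high-confidence scores) plus a preferential-attachment periphery with
    lower scores, so a 0.9 score cut plus median screening should recover the
    core.  Survival cohorts plant proportional-hazards effects for designated
    genes on top of exponential event times with uniform censoring.
    """

    seed: int = 0
    # compounds
    n_compounds: int = 100
    ob_mean: float = 50.0
    ob_sd: float = 15.0
    dl_a: float = 2.0
    dl_b: float = 3.0
    # drug targets / disease genes
    n_drug_targets: int = 216
    n_disease_genes: int = 2000
    overlap_size: int = 150
    n_disease_sources: int = 5
    source_coverage: float = 0.6
    # ppi
    ppi_n_core: int = 20
    ppi_n_periphery: int = 80
    ppi_core_p: float = 0.7
    ppi_attach_degree: int = 2
    # annotations
    n_terms: int = 200
    term_size_min: int = 10
    term_size_max: int = 60
    n_planted_terms: int = 1
    planted_fraction: float = 0.8
    # survival
    n_patients: int = 200
    baseline_hazard: float = 1.0 / 1500.0  # per day; mean survival ~4 years
    hazard_ratios: tuple[tuple[str, float], ...] = (("PLANTED1", 3.0),)
    n_null_genes: int = 50
    censor_fraction: float = 0.3

    def __post_init__(self) -> None:
        counts = (self.n_compounds, self.n_drug_targets, self.n_disease_genes,
                  self.ppi_n_core, self.n_terms, self.n_patients)
        if any(c < 0 for c in counts):
            raise ValueError("counts must be nonnegative")
        if self.ob_sd <= 0 or self.dl_a <= 0 or self.dl_b <= 0:
            raise ValueError("invalid OB/DL distribution parameters")
        if not 0 <= self.censor_fraction <= 1 or not 0 <= self.planted_fraction <= 1:
            raise ValueError("fractions must lie in [0, 1]")
        if not 0 <= self.ppi_core_p <= 1:
            raise ValueError("core edge probability must lie in [0, 1]")
        if any(hr <= 0 for _, hr in self.hazard_ratios):
            raise ValueError("hazard ratios must be positive")
        if self.overlap_size > min(self.n_drug_targets, self.n_disease_genes):
            raise ValueError("overlap_size exceeds a gene pool")


def gen_compounds(config: SynthConfig, herb: str = "synthherb") -> list[Compound]:
    """Synthetic ADME table: OB ~ TruncNormal(mean, sd; [0, 100]), DL ~ Beta(a, b)."""
    rng = _rng(config, "compounds")
    out: list[Compound] = []
    n = config.n_compounds
    # rejection-sample the truncated normal; the acceptance region is wide
    ob = np.empty(0)
    while ob.size < n:
        draw = rng.normal(config.ob_mean, config.ob_sd, size=2 * n)
        ob = np.concatenate([ob, draw[(draw >= 0) & (draw <= 100)]])
    dl = rng.beta(config.dl_a, config.dl_b, size=n)
    for i in range(n):
        out.append(Compound(f"SYN{i:05d}", f"synthetic-compound-{i}", float(ob[i]), float(dl[i]), herb))
    return out


def gen_drug_disease(
    config: SynthConfig, compounds: list[Compound] | None = None
) -> tuple[TargetMap, list[GeneSet], dict]:
    """Compound-target map plus multi-source disease gene lists.

    ``overlap_size`` shared symbols are planted in both the drug-target pool
    and the disease pool; each disease source samples ``source_coverage`` of
    the disease pool, so the realized drug-disease intersection (reported in
    the ground-truth dict) is close to, but can fall slightly below, the
    planted size.
    """
    if compounds is None:
        compounds = gen_compounds(config)
    shared = [f"SH{i:04d}" for i in range(config.overlap_size)]
    drug_only = [f"TG{i:04d}" for i in range(config.n_drug_targets - config.overlap_size)]
    disease_only = [f"DZ{i:05d}" for i in range(config.n_disease_genes - config.overlap_size)]
    drug_pool = shared + drug_only
    disease_pool = shared + disease_only

    rng = _rng(config, "targets")
    mols = [c.mol_id for c in compounds]
    pairs: set[tuple[str, str]] = set()
    for gene in drug_pool:  # every target reachable from >= 1 compound
        k = 1 + rng.poisson(1.0)
        for m in rng.choice(mols, size=min(k, len(mols)), replace=False):
            pairs.add((str(m), gene))
    target_map = TargetMap(frozenset(pairs))

    rng_d = _rng(config, "disease")
    n_per = int(round(config.source_coverage * len(disease_pool)))
    sources = []
    for s in range(config.n_disease_sources):
        picked = rng_d.choice(disease_pool, size=n_per, replace=False)
        sources.append(GeneSet(f"source{s + 1}", frozenset(str(g) for g in picked)))
    disease_union = frozenset().union(*(s.symbols for s in sources))
    truth = {
        "planted_overlap": sorted(shared),
        "realized_overlap": sorted(set(shared) & disease_union & target_map.all_targets().symbols),
    }
    return target_map, sources, truth


def gen_ppi(
    config: SynthConfig, node_names: list[str] | None = None
) -> tuple[list[ScoredEdge], list[str]]:
    """Scored edge list with a planted dense core.

    Core: Erdos-Renyi on ``ppi_n_core`` nodes at ``ppi_core_p``, edge scores
    U(0.9, 1.0).  Periphery: nodes added one at a time, each attaching to
    ``ppi_attach_degree`` existing nodes with probability proportional to
    degree + 1; involved scores U(0.4, 0.95).  Returns the edges and the
    planted-core node ids.
    """
    rng = _rng(config, "ppi")
    n_core, n_per = config.ppi_n_core, config.ppi_n_periphery
    n = n_core + n_per
    if node_names is None:
        names = [f"CORE{i:03d}" for i in range(n_core)] + [f"PER{i:04d}" for i in range(n_per)]
    else:
        if len(node_names) < n:
            raise ValueError(f"need {n} node names, got {len(node_names)}")
        names = list(node_names[:n])
    core = names[:n_core]

    edges: list[ScoredEdge] = []
    for i in range(n_core):
        for j in range(i + 1, n_core):
            if rng.random() < config.ppi_core_p:
                edges.append(ScoredEdge(names[i], names[j], float(rng.uniform(0.9, 1.0))))
    degree = {v: 0 for v in names[:n_core]}
    for e in edges:
        degree[e.a] += 1
        degree[e.b] += 1
    for i in range(n_core, n):
        existing = names[:i]
        w = np.array([degree[v] + 1.0 for v in existing])
        k = min(config.ppi_attach_degree, len(existing))
        chosen = rng.choice(existing, size=k, replace=False, p=w / w.sum())
        degree[names[i]] = 0
        for u in chosen:
            edges.append(ScoredEdge(names[i], str(u), float(rng.uniform(0.4, 0.95))))
            degree[names[i]] += 1
            degree[str(u)] += 1
    return edges, core


def gen_annotations(
    config: SynthConfig, query: GeneSet, universe: GeneSet
) -> tuple[AnnotationCollection, list[str]]:
    """GMT-style collection: uniform decoy terms plus planted enriched terms.

    Each planted term absorbs ``planted_fraction`` of the query, padded with
    non-query genes up to a size drawn from the configured range; decoys are
    uniform draws from the universe.
    """
    if not query.symbols <= universe.symbols:
        raise ValueError("query must be a subset of the universe")
    if config.term_size_max > len(universe.symbols):
        raise ValueError("term size range exceeds the universe")
    rng = _rng(config, "annotations")
    uni = sorted(universe.symbols)
    qry = sorted(query.symbols)
    non_query = sorted(universe.symbols - query.symbols)

    terms: dict[str, tuple[str, frozenset[str]]] = {}
    planted_ids: list[str] = []
    for i in range(config.n_planted_terms):
        tid = f"PLANTED:{i + 1:04d}"
        n_from_query = max(1, int(round(config.planted_fraction * len(qry))))
        size = int(rng.integers(config.term_size_min, config.term_size_max + 1))
        members = set(rng.choice(qry, size=min(n_from_query, len(qry)), replace=False))
        n_pad = max(0, size - len(members))
        if n_pad and non_query:
            members |= set(rng.choice(non_query, size=min(n_pad, len(non_query)), replace=False))
        planted_ids.append(tid)
        terms[tid] = (f"planted term {i + 1}", frozenset(str(g) for g in members))
    for i in range(config.n_terms):
        size = int(rng.integers(config.term_size_min, config.term_size_max + 1))
        members = rng.choice(uni, size=size, replace=False)
        terms[f"DECOY:{i + 1:04d}"] = (f"decoy term {i + 1}", frozenset(str(g) for g in members))
    return AnnotationCollection("PATHWAY", terms), planted_ids


def gen_survival(config: SynthConfig, genes: list[str] | None = None) -> tuple[SurvivalCohort, list[str]]:
    """Clinical table + expression matrix with planted prognostic genes.

    Expression is standard normal.  Each patient's event hazard is the
    baseline multiplied by the configured hazard ratio for every planted gene
    on which the patient sits above the cohort median; event times are
    exponential and an exact ``censor_fraction`` of patients is censored at a
    uniform point before their event.
    """
    rng = _rng(config, "survival")
    planted = [g for g, _ in config.hazard_ratios]
    hr = dict(config.hazard_ratios)
    if genes is None:
        genes = planted + [f"NULL{i:04d}" for i in range(config.n_null_genes)]
    missing = [g for g in planted if g not in genes]
    if missing:
        raise ValueError(f"planted genes absent from gene list: {missing}")
    n = config.n_patients
    ids = [f"PT{i:04d}" for i in range(n)]
    expr = pd.DataFrame(rng.standard_normal((n, len(genes))), index=ids, columns=genes)
    expr.index.name = "patient_id"

    log_hazard = np.full(n, np.log(config.baseline_hazard))
    for g in planted:
        high = expr[g].to_numpy() > np.median(expr[g].to_numpy())
        log_hazard += high * np.log(hr[g])
    t_event = rng.exponential(1.0 / np.exp(log_hazard))
    event = np.ones(n, dtype=int)
    n_cens = int(round(config.censor_fraction * n))
    cens_idx = rng.choice(n, size=n_cens, replace=False)
    times = t_event.copy()
    times[cens_idx] = rng.uniform(0, t_event[cens_idx])
    event[cens_idx] = 0
    clin = pd.DataFrame({"patient_id": ids, "time": times, "event": event})
    return SurvivalCohort(clin, expr), planted


def generate_bundle(config: SynthConfig, outdir: str | Path) -> dict:
    """Write a complete, mutually consistent input bundle plus ground truth.

    The PPI is laid over the realized drug-disease overlap genes (core first),
    the annotation collection plants its signal in that overlap, and the
    survival cohort plants hazard ratios on the first few PPI-core genes — so
    a full pipeline run on the bundle can be scored end to end against
    ``ground_truth.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    compounds = gen_compounds(config)
    half = len(compounds) // 2
    herb_a = [Compound(c.mol_id, c.name, c.ob, c.dl, "synthherbA") for c in compounds[:half]]
    herb_b = [Compound(c.mol_id, c.name, c.ob, c.dl, "synthherbB") for c in compounds[half:]]
    write_compound_table(herb_a, outdir / "herbA_components.tsv")
    write_compound_table(herb_b, outdir / "herbB_components.tsv")

    target_map, sources, dd_truth = gen_drug_disease(config, compounds)
    target_map.write(outdir / "targets.tsv")
    for s in sources:
        (outdir / f"disease_{s.label}.txt").write_text("\n".join(s.sorted()) + "\n", encoding="utf-8")

    overlap = dd_truth["realized_overlap"]
    n_ppi = config.ppi_n_core + config.ppi_n_periphery
    if len(overlap) < n_ppi:
        raise ValueError(
            f"realized overlap ({len(overlap)}) smaller than the PPI ({n_ppi}); "
            "increase overlap_size or shrink the PPI"
        )
    edges, core = gen_ppi(config, node_names=overlap)
    with (outdir / "ppi_edges.tsv").open("w", encoding="utf-8") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for e in edges:
            fh.write(f"{e.a}\t{e.b}\t{e.score:.6f}\n")

    universe = GeneSet("universe", target_map.all_targets().symbols
                       | frozenset().union(*(s.symbols for s in sources)))
    query = GeneSet("overlap", frozenset(overlap))
    collection, planted_terms = gen_annotations(config, query, universe)
    write_gmt(collection, outdir / "annotations.gmt")

    planted_survival = [(core[i], hr) for i, (_, hr) in enumerate(config.hazard_ratios)]
    surv_cfg = SynthConfig(**{**asdict(config), "hazard_ratios": tuple(planted_survival)})
    cohort, planted_genes = gen_survival(surv_cfg, genes=sorted(set(overlap)))
    cohort.clinical.to_csv(outdir / "clinical.tsv", sep="\t", index=False)
    cohort.expression.to_csv(outdir / "expression.tsv", sep="\t")

    truth = {
        "seed": config.seed,
        "planted_overlap": dd_truth["planted_overlap"],
        "realized_overlap": overlap,
        "ppi_core": core,
        "planted_terms": planted_terms,
        "planted_prognostic_genes": planted_genes,
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2) + "\n", encoding="utf-8")
    return truth
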