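"""Protein-protein interaction topology: graph construction from a scored
edge list, six node-centrality metrics, and median-threshold hub extraction.

The screening convention follows the CytoNCA family of topological filters:
compute Degree (DC), Betweenness (BC), Closeness (CC), Eigenvector (EC),
Local Average Connectivity (LAC) and Network Centrality (NC) for every node,
then retain the nodes strictly above the median on every configured metric,
optionally iterating on the induced subgraph.

Metric definitions
------------------
DC(v)   node degree.
BC(v)   unnormalized shortest-path betweenness, sum over unordered pairs
        s != v != t of sigma_st(v) / sigma_st.
CC(v)   Wasserman-Faust closeness, (s-1)^2 / ((n-1) * sum_u d(v,u)) with s
        the size of v's connected component; equals (n-1)/sum d on connected
        graphs.
EC(v)   component of the principal eigenvector of the adjacency matrix,
        nonnegative and normalized to unit maximum.
LAC(v)  mean degree of v's neighbors within the subgraph they induce
        (v excluded).
NC(v)   sum over neighbors u of the edge clustering coefficient
        ECC(v,u) = z(v,u) / min(deg v - 1, deg u - 1), where z counts the
        triangles on edge (v,u); ECC := 0 when the denominator is zero.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ScoredEdge",
    "ScreenConfig",
    "ScreenRound",
    "ScreenResult",
    "read_scored_edges",
    "build_network",
    "compute_centralities",
    "eigenvector_scores",
    "screen_core",
    "read_centrality_table",
    "load_packaged_table3",
    "write_centrality_table",
    "export_graphml",
    "export_sif",
]

METRICS = ("dc", "bc", "cc", "ec", "lac", "nc")

#: CSV column names in the conventional report order.
_METRIC_COLUMNS = {
    "bc": "Betweenness",
    "cc": "Closeness",
    "dc": "Degree",
    "ec": "Eigenvector",
    "lac": "LAC",
    "nc": "Network",
}
_REPORT_ORDER = ["Betweenness", "Closeness", "Degree", "Eigenvector", "LAC", "Network"]


@dataclass(frozen=True)
class ScoredEdge:
    """Undirected interaction with a confidence score in [0, 1]."""

    a: str
    b: str
    score: float

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError(f"self-loop on {self.a!r}")
        if not 0 <= self.score <= 1:
            raise ValueError(f"edge ({self.a}, {self.b}): score {self.score} outside [0, 1]")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.a, self.b) if self.a <= self.b else (self.b, self.a)


def read_scored_edges(path: str | Path) -> list[ScoredEdge]:
    """Read a 3-column TSV (protein1, protein2, combined_score).

    STRING-style integer scores on the 0-1000 scale are auto-detected (any
    score > 1) and divided by 1000.
    """
    rows: list[tuple[str, str, float]] = []
    with Path(path).open(encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0].lower() in {"protein1", "node1"}:
                continue
            rows.append((row[0].strip(), row[1].strip(), float(row[2])))
    scale = 1000.0 if any(s > 1 for *_, s in rows) else 1.0
    return [ScoredEdge(a, b, s / scale) for a, b, s in rows]


def build_network(edges: Iterable[ScoredEdge], min_score: float = 0.9) -> nx.Graph:
    """Keep edges with score >= min_score; drop nodes left isolated.

    Nodes with no surviving interaction ("unrelated nodes") do not appear in
    the result, so the graph has no degree-0 vertices.
    """
    g = nx.Graph()
    for e in edges:
        if e.score >= min_score:
            a, b = e.pair
            g.add_edge(a, b, score=e.score)
    return g


def eigenvector_scores(
    g: nx.Graph,
    nodelist: Sequence[str] | None = None,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Principal-eigenvector scores by shifted power iteration.

    Iterates x <- (A + I) x from the uniform vector; the shift keeps the
    iteration convergent on bipartite graphs, where A's extreme eigenvalues
    are symmetric.  The result is nonnegative and normalized to unit maximum.
    """
    nodelist = list(nodelist) if nodelist is not None else list(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodelist, weight=None)
    n = a.shape[0]
    if n == 0:
        return np.array([])
    x = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        y = a @ x + x
        y /= np.linalg.norm(y)
        if np.linalg.norm(y - x) < tol:
            x = y
            break
        x = y
    x = np.abs(x)
    m = x.max()
    return x / m if m > 0 else x


def _triangle_counts(g: nx.Graph) -> dict[tuple[str, str], int]:
    """Number of triangles on each edge = size of the endpoints' common neighborhood."""
    adj = {v: set(g[v]) for v in g}
    return {(u, v): len(adj[u] & adj[v]) for u, v in g.edges}


def compute_centralities(g: nx.Graph, metrics: Sequence[str] = METRICS) -> pd.DataFrame:
    """One row per node with the requested centrality columns (lowercase keys)."""
    if g.number_of_nodes() == 0:
        raise ValueError("cannot compute centralities of an empty network")
    unknown = set(metrics) - set(METRICS)
    if unknown:
        raise ValueError(f"unknown metrics: {sorted(unknown)}")
    nodes = list(g.nodes)
    out = pd.DataFrame(index=pd.Index(nodes, name="node"))
    if "dc" in metrics:
        out["dc"] = [g.degree(v) for v in nodes]
    if "bc" in metrics:
        bc = nx.betweenness_centrality(g, normalized=False)
        out["bc"] = [bc[v] for v in nodes]
    if "cc" in metrics:
        cc = nx.closeness_centrality(g, wf_improved=True)
        out["cc"] = [cc[v] for v in nodes]
    if "ec" in metrics:
        out["ec"] = eigenvector_scores(g, nodelist=nodes)
    if "lac" in metrics or "nc" in metrics:
        tri = _triangle_counts(g)
        tri.update({(v, u): z for (u, v), z in tri.items()})
        if "lac" in metrics:
            lac = []
            for v in nodes:
                nbrs = list(g[v])
                # sum of induced-subgraph degrees = 2 * edges among neighbors
                # = sum over incident edges of their triangle count
                lac.append(sum(tri[(v, u)] for u in nbrs) / len(nbrs) if nbrs else 0.0)
            out["lac"] = lac
        if "nc" in metrics:
            nc = []
            for v in nodes:
                dv = g.degree(v)
                total = 0.0
                for u in g[v]:
                    denom = min(dv - 1, g.degree(u) - 1)
                    if denom > 0:
                        total += tri[(v, u)] / denom
                nc.append(total)
            out["nc"] = nc
    return out[list(metrics)]


@dataclass(frozen=True)
class ScreenConfig:
    """Median-screening configuration.

    ``rounds`` is a positive integer or ``"until-stable"``; ``strict`` selects
    strictly-greater-than-median retention (ties excluded) versus >=.
    """

    metrics: tuple[str, ...] = METRICS
    rounds: int | Literal["until-stable"] = 1
    strict: bool = True

    def __post_init__(self) -> None:
        if not self.metrics:
            raise ValueError("at least one screening metric is required")
        unknown = set(self.metrics) - set(METRICS)
        if unknown:
            raise ValueError(f"unknown metrics: {sorted(unknown)}")
        if self.rounds != "until-stable" and (not isinstance(self.rounds, int) or self.rounds < 1):
            raise ValueError("rounds must be a positive integer or 'until-stable'")


@dataclass(frozen=True)
class ScreenRound:
    medians: dict[str, float]
    table: pd.DataFrame
    retained: tuple[str, ...]


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of iterated median screening.

    ``terminal`` is True when a round would have retained the empty set (for
    example on a vertex-transitive graph, where every metric ties at its
    median); in that case ``retained`` is that round's input node set.
    """

    retained: tuple[str, ...]
    rounds: tuple[ScreenRound, ...] = field(default_factory=tuple)
    terminal: bool = False


def screen_core(g: nx.Graph, config: ScreenConfig = ScreenConfig()) -> ScreenResult:
    """Iteratively retain nodes above the median on every configured metric."""
    if g.number_of_nodes() == 0:
        raise ValueError("cannot screen an empty network")
    current = g
    rounds: list[ScreenRound] = []
    n_rounds = np.inf if config.rounds == "until-stable" else config.rounds
    while len(rounds) < n_rounds:
        table = compute_centralities(current, config.metrics)
        medians = {m: float(np.median(table[m].to_numpy())) for m in config.metrics}
        if config.strict:
            mask = np.all([table[m].to_numpy() > medians[m] for m in config.metrics], axis=0)
        else:
            mask = np.all([table[m].to_numpy() >= medians[m] for m in config.metrics], axis=0)
        retained = tuple(sorted(table.index[mask]))
        if not retained:
            rounds.append(ScreenRound(medians, table, tuple(sorted(current.nodes))))
            return ScreenResult(tuple(sorted(current.nodes)), tuple(rounds), terminal=True)
        rounds.append(ScreenRound(medians, table, retained))
        stable = set(retained) == set(current.nodes)
        current = current.subgraph(retained).copy()
        if stable:
            break
    return ScreenResult(tuple(sorted(current.nodes)), tuple(rounds), terminal=False)


# ---------------------------------------------------------------------------
# Tabular and network I/O


def write_centrality_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a centrality table as CSV in the conventional column order."""
    df = table.rename(columns=_METRIC_COLUMNS)
    cols = [c for c in _REPORT_ORDER if c in df.columns]
    df = df[cols]
    df.index.name = "name"
    df.to_csv(path)


def read_centrality_table(path: str | Path) -> pd.DataFrame:
    """Read a centrality CSV (name, Betweenness, ..., Network) back to lowercase keys."""
    df = pd.read_csv(path, index_col="name")
    df.index.name = "node"
    inv = {v: k for k, v in _METRIC_COLUMNS.items()}
    return df.rename(columns=inv)


def load_packaged_table3() -> pd.DataFrame:
    """The packaged 44-row core-target centrality table."""
    with resources.as_file(resources.files("herbnet.data").joinpath("table3_core_targets.csv")) as p:
        return read_centrality_table(p)


def export_graphml(g: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(g, str(path))


def export_sif(g: nx.Graph, path: str | Path, relation: str = "pp") -> None:
    """Simple-interaction format: one 'a <relation> b' line per edge."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in g.edges):
            fh.write(f"{u}\t{relation}\t{v}\n")
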