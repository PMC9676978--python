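"""Over-representation analysis (ORA) of a query gene set against annotation
term collections (GO-style BP/CC/MF or pathway sets) with Benjamini-Hochberg
false-discovery-rate control.

For each term with K members in an N-gene universe and a query of n genes of
which k fall in the term, the enrichment p-value is the hypergeometric upper
tail P(X >= k).  Unless a background is supplied, the universe defaults to
all genes appearing in the annotation collection — the standard ORA default,
stated here because results depend on it.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .geneset_ops import GeneSet

__all__ = [
    "AnnotationCollection",
    "EnrichmentResult",
    "read_gmt",
    "write_gmt",
    "hypergeom_upper_p",
    "bh_adjust",
    "enrich",
    "results_to_frame",
]

logger = logging.getLogger(__name__)

CATEGORIES = ("BP", "CC", "MF", "PATHWAY")


@dataclass(frozen=True)
class AnnotationCollection:
    """A category label plus term-id -> (term name, member gene set)."""

    category: str
    terms: Mapping[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"category must be one of {CATEGORIES}, got {self.category!r}")
        for tid, (_, genes) in self.terms.items():
            if not genes:
                raise ValueError(f"term {tid!r} has an empty gene set")

    def all_genes(self) -> frozenset[str]:
        return frozenset().union(*(g for _, g in self.terms.values()))


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    category: str
    k: int  # query genes in term
    K: int  # term size within universe
    n: int  # query size within universe
    N: int  # universe size
    p: float
    q: float


def read_gmt(path: str | Path, category: str = "PATHWAY") -> AnnotationCollection:
    """Read a GMT file: term_id <tab> description <tab> gene1 <tab> gene2 ..."""
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            tid = parts[0]
            if tid in terms:
                raise ValueError(f"duplicate term id {tid!r} in {path}")
            genes = frozenset(g.strip().upper() for g in parts[2:] if g.strip())
            terms[tid] = (parts[1], genes)
    return AnnotationCollection(category, terms)


def write_gmt(collection: AnnotationCollection, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for tid in sorted(collection.terms):
            name, genes = collection.terms[tid]
            fh.write("\t".join([tid, name, *sorted(genes)]) + "\n")


def hypergeom_upper_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"invalid hypergeometric parameters k={k}, K={K}, n={n}, N={N}")
    # sf(k-1) = P(X >= k); scipy evaluates the tail in log space.
    return float(min(1.0, hypergeom.sf(k - 1, N, K, n)))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order, capped at 1."""
    if len(pvalues) == 0:
        return []
    if any(not (0 < p <= 1) for p in pvalues):
        raise ValueError("p-values must lie in (0, 1]")
    return list(multipletests(pvalues, method="fdr_bh")[1])


def enrich(
    query: GeneSet,
    collection: AnnotationCollection,
    universe: GeneSet | None = None,
    p_max: float = 0.05,
    q_max: float = 0.05,
    top_n: int | None = None,
) -> list[EnrichmentResult]:
    """Hypergeometric ORA of ``query`` against every term in ``collection``.

    Query genes outside the universe are dropped with a logged warning.  The
    BH adjustment is computed over all tested terms; results are then
    filtered to p <= p_max and q <= q_max, sorted ascending by p with ties
    broken by term_id, and truncated to ``top_n``.
    """
    bg = frozenset(universe.symbols) if universe is not None else collection.all_genes()
    if not bg:
        raise ValueError("enrichment universe is empty")
    q_genes = query.symbols & bg
    dropped = len(query.symbols) - len(q_genes)
    if dropped:
        logger.warning("%d query gene(s) outside the universe were dropped", dropped)
    N, n = len(bg), len(q_genes)

    rows = []
    for tid in sorted(collection.terms):
        name, genes = collection.terms[tid]
        term_in_bg = genes & bg
        if not term_in_bg:
            continue
        K = len(term_in_bg)
        k = len(term_in_bg & q_genes)
        rows.append((tid, name, k, K, hypergeom_upper_p(k, K, n, N)))
    qvals = bh_adjust([r[4] for r in rows])
    results = [
        EnrichmentResult(tid, name, collection.category, k, K, n, N, p, qv)
        for (tid, name, k, K, p), qv in zip(rows, qvals)
        if p <= p_max and qv <= q_max
    ]
    results.sort(key=lambda r: (r.p, r.term_id))
    return results[:top_n] if top_n is not None else results


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Results as a DataFrame with columns term_id, name, category, k, K, n, N, p, q."""
    return pd.DataFrame(
        [(r.term_id, r.term_name, r.category, r.k, r.K, r.n, r.N, r.p, r.q) for r in results],
        columns=["term_id", "name", "category", "k", "K", "n", "N", "p", "q"],
    )
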