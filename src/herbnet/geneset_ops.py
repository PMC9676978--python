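"""Gene-set plumbing: symbol normalization, multi-source unions, intersections
and Venn region counts.

Disease genes come from several curated sources (OMIM-, PharmGkb-, GeneCards-,
TTD-, DrugBank-style lists); the screen takes their union and intersects it
with the drug's target genes.  All operations are plain set algebra on
normalized (trimmed, uppercased) symbols, with deterministic lexicographic
output ordering so artifacts are byte-reproducible.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from itertools import combinations, product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GeneSet",
    "TargetMap",
    "normalize_symbols",
    "read_gene_list",
    "read_alias_table",
    "union_sources",
    "intersect_drug_disease",
    "venn_counts",
]


@dataclass(frozen=True)
class GeneSet:
    """A labelled set of uppercase gene symbols."""

    label: str
    symbols: frozenset[str]

    def __post_init__(self) -> None:
        if any(not s for s in self.symbols):
            raise ValueError(f"GeneSet {self.label!r} contains an empty symbol")
        object.__setattr__(self, "symbols", frozenset(self.symbols))

    def __len__(self) -> int:
        return len(self.symbols)

    def sorted(self) -> list[str]:
        return sorted(self.symbols)


@dataclass(frozen=True)
class TargetMap:
    """Compound -> gene-symbol bipartite relation as a set of (mol_id, symbol) pairs."""

    edges: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", frozenset(self.edges))

    def all_targets(self, label: str = "drug_targets") -> GeneSet:
        return GeneSet(label, frozenset(g for _, g in self.edges))

    def targets_of(self, mol_id: str) -> set[str]:
        return {g for m, g in self.edges if m == mol_id}

    @classmethod
    def read(cls, path: str | Path) -> "TargetMap":
        """Read a two-column TSV (mol_id, gene symbol); symbols are normalized."""
        pairs: set[tuple[str, str]] = set()
        with Path(path).open(encoding="utf-8") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or not row[0].strip() or row[0].startswith("#"):
                    continue
                mol, gene = row[0].strip(), row[1].strip().upper()
                if gene:
                    pairs.add((mol, gene))
        return cls(frozenset(pairs))

    def write(self, path: str | Path) -> None:
        with Path(path).open("w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, delimiter="\t")
            for mol, gene in sorted(self.edges):
                w.writerow([mol, gene])


def normalize_symbols(
    raw: Iterable[str], alias_map: Mapping[str, str] | None = None
) -> set[str]:
    """Trim, uppercase and de-duplicate symbols, applying an optional alias map.

    The alias map (alias -> canonical symbol, both compared case-insensitively)
    stands in for a UniProt name-to-symbol conversion.  Hyphens and dots are
    preserved; only case and surrounding whitespace are collapsed.
    """
    aliases = {a.strip().upper(): s.strip().upper() for a, s in (alias_map or {}).items()}
    out: set[str] = set()
    for s in raw:
        s = s.strip().upper()
        if s:
            out.add(aliases.get(s, s))
    return out


def read_gene_list(path: str | Path, label: str | None = None,
                   alias_map: Mapping[str, str] | None = None) -> GeneSet:
    """Read a one-symbol-per-line gene list into a normalized GeneSet."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    return GeneSet(label or path.stem, frozenset(normalize_symbols(lines, alias_map)))


def read_alias_table(path: str | Path) -> dict[str, str]:
    """Read a two-column (alias, symbol) TSV; conflicting aliases are an error."""
    mapping: dict[str, str] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or not row[0].strip():
                continue
            alias, symbol = row[0].strip().upper(), row[1].strip().upper()
            if alias in mapping and mapping[alias] != symbol:
                raise ValueError(f"alias {alias!r} maps to both {mapping[alias]!r} and {symbol!r}")
            mapping[alias] = symbol
    return mapping


def union_sources(
    sources: Sequence[GeneSet], label: str = "union"
) -> tuple[GeneSet, dict[str, int], dict[tuple[str, str], int]]:
    """Union several disease-gene sources.

    Returns the union set, per-source cardinalities, and pairwise overlap
    counts keyed by (label_i, label_j) in input order.
    """
    if not sources:
        raise ValueError("union_sources requires at least one source")
    union = frozenset().union(*(s.symbols for s in sources))
    per_source = {s.label: len(s.symbols) for s in sources}
    pairwise = {
        (a.label, b.label): len(a.symbols & b.symbols)
        for a, b in combinations(sources, 2)
    }
    return GeneSet(label, union), per_source, pairwise


def intersect_drug_disease(drug_targets: GeneSet, disease: GeneSet,
                           label: str = "intersection") -> GeneSet:
    """Exact intersection of drug targets with disease genes."""
    return GeneSet(label, drug_targets.symbols & disease.symbols)


def venn_counts(sets: Sequence[GeneSet]) -> dict[tuple[int, ...], int]:
    """Count elements in every Venn region of 2-5 sets.

    Keys are membership patterns, e.g. (1, 0, 1) = in sets 1 and 3 only, in
    input order.  The all-zero region is omitted; counts sum to |union|.
    """
    if not 2 <= len(sets) <= 5:
        raise ValueError(f"venn_counts supports 2-5 sets, got {len(sets)}")
    union = frozenset().union(*(s.symbols for s in sets))
    counts = {p: 0 for p in product((0, 1), repeat=len(sets)) if any(p)}
    for g in union:
        counts[tuple(int(g in s.symbols) for s in sets)] += 1
    return counts


def write_venn_counts(counts: Mapping[tuple[int, ...], int],
                      labels: Sequence[str], path: str | Path) -> None:
    """Emit Venn region counts as CSV with one indicator column per set."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow([*labels, "count"])
        for pattern in sorted(counts, reverse=True):
            w.writerow([*pattern, counts[pattern]])
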