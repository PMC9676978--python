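"""Ingest and rank molecular-docking affinity tables.

Docking itself (receptor preparation, pose search) is outside this package's
scope; affinities arrive as a table of predicted binding free energies in
kcal/mol, where more negative means a more stable complex.  "Best" therefore
always means the minimum affinity.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

__all__ = [
    "DockingRecord",
    "read_docking_table",
    "write_docking_table",
    "load_packaged_docking",
    "rank_docking",
]

_PDB_ID = re.compile(r"^[0-9A-Za-z]{4}$")


@dataclass(frozen=True)
class DockingRecord:
    """One target-compound docking outcome; affinity in kcal/mol."""

    target: str
    compound: str
    affinity: float
    pdb_id: str | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.affinity):
            raise ValueError(f"{self.target}-{self.compound}: affinity must be finite")
        if self.pdb_id is not None and not _PDB_ID.match(self.pdb_id):
            raise ValueError(f"invalid PDB id {self.pdb_id!r}")


def read_docking_table(path: str | Path) -> list[DockingRecord]:
    """Read a CSV with columns target, compound, affinity_kcal_mol (pdb_id optional)."""
    path = Path(path)
    records: list[DockingRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return []
        cols = {c.lower().strip(): c for c in reader.fieldnames}
        for key in ("target", "compound"):
            if key not in cols:
                raise ValueError(f"docking table is missing column {key!r}")
        aff_col = next((cols[c] for c in ("affinity_kcal_mol", "affinity") if c in cols), None)
        if aff_col is None:
            raise ValueError("docking table is missing an affinity column")
        for row_no, row in enumerate(reader, start=2):
            try:
                affinity = float(row[aff_col])
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path.name} row {row_no}: non-numeric affinity") from exc
            pdb = (row.get(cols.get("pdb_id", ""), "") or "").strip() or None
            records.append(DockingRecord(row[cols["target"]].strip(), row[cols["compound"]].strip(),
                                         affinity, pdb))
    return records


def write_docking_table(records: Sequence[DockingRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["target", "pdb_id", "compound", "affinity_kcal_mol"])
        for r in records:
            w.writerow([r.target, r.pdb_id or "", r.compound, r.affinity])


def load_packaged_docking() -> list[DockingRecord]:
    """The packaged 9-row target-compound affinity table."""
    with resources.as_file(resources.files("herbnet.data").joinpath("table4_docking.csv")) as p:
        return read_docking_table(p)


def rank_docking(
    records: Sequence[DockingRecord], per_target: bool = False
) -> list[DockingRecord] | tuple[list[DockingRecord], dict[str, DockingRecord]]:
    """Sort ascending by affinity (strongest binder first).

    Ties break lexicographically by (target, compound) so the order is a
    deterministic permutation of the input.  With ``per_target`` also return
    each target's minimum-affinity record.
    """
    ranked = sorted(records, key=lambda r: (r.affinity, r.target, r.compound))
    if not per_target:
        return ranked
    best: dict[str, DockingRecord] = {}
    for r in ranked:
        best.setdefault(r.target, r)
    return ranked, best
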