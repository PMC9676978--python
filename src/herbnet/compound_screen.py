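"""ADME screening of herbal ingredients.

Traditional-medicine injections are mixtures of many plant metabolites; only
compounds that are orally bioavailable and drug-like are considered plausible
systemic actors.  The conventional TCMSP-style screen keeps compounds with
oral bioavailability (OB) >= 30% and drug-likeness (DL) >= 0.18.  This module
reads per-herb compound tables and applies that filter.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Compound",
    "AdmeThresholds",
    "CompoundTableError",
    "read_compound_table",
    "load_packaged_herb",
    "filter_compounds",
    "write_compound_table",
]


class CompoundTableError(ValueError):
    """Raised for malformed compound tables (missing columns, bad numbers)."""


@dataclass(frozen=True)
class Compound:
    """One herbal ingredient with its ADME descriptors.

    ``ob`` is on the percent scale (42.36 means 42.36%); ``dl`` is a unitless
    score in [0, 1].  ``herb`` records which herb table the row came from; the
    same molecule listed under two herbs yields two records.
    """

    mol_id: str
    name: str
    ob: float
    dl: float
    herb: str

    def __post_init__(self) -> None:
        if not self.mol_id:
            raise CompoundTableError("mol_id must be nonempty")
        if not (self.ob >= 0 and math.isfinite(self.ob)):
            raise CompoundTableError(f"{self.mol_id}: OB must be finite and >= 0, got {self.ob}")
        if not (0 <= self.dl <= 1):
            raise CompoundTableError(f"{self.mol_id}: DL must lie in [0, 1], got {self.dl}")


@dataclass(frozen=True)
class AdmeThresholds:
    """Inclusive lower bounds for the ADME filter (defaults: OB 30%, DL 0.18)."""

    ob_min: float = 30.0
    dl_min: float = 0.18

    def __post_init__(self) -> None:
        if self.ob_min < 0 or self.dl_min < 0:
            raise ValueError("ADME thresholds must be nonnegative")


# Accepted header spellings, case-insensitive.
_COLUMN_ALIASES = {
    "mol_id": {"molid", "mol_id", "mol id", "id"},
    "name": {"molecule_name", "molecule name", "name", "molecule"},
    "ob": {"ob", "ob (%)", "ob%"},
    "dl": {"dl"},
}


def _detect_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def _resolve_columns(header: Sequence[str]) -> dict[str, int]:
    lowered = [h.strip().lower() for h in header]
    out: dict[str, int] = {}
    for key, aliases in _COLUMN_ALIASES.items():
        for i, h in enumerate(lowered):
            if h in aliases:
                out[key] = i
                break
        else:
            raise CompoundTableError(f"compound table is missing a column for {key!r} (header: {list(header)})")
    return out


def read_compound_table(path: str | Path, herb: str) -> list[Compound]:
    """Read a TSV/CSV compound table, attaching ``herb`` to every row.

    The delimiter is auto-detected from the header line.  Row order is
    preserved.  Duplicate (mol_id, herb) pairs are rejected.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        first = fh.readline()
        if not first.strip():
            return []
        delim = _detect_delimiter(first)
        cols = _resolve_columns(next(csv.reader([first], delimiter=delim)))
        compounds: list[Compound] = []
        seen: set[str] = set()
        for row_no, row in enumerate(csv.reader(fh, delimiter=delim), start=2):
            if not row or not "".join(row).strip():
                continue
            try:
                ob = float(row[cols["ob"]])
                dl = float(row[cols["dl"]])
            except (ValueError, IndexError) as exc:
                raise CompoundTableError(f"{path.name} row {row_no}: non-numeric OB/DL ({exc})") from exc
            mol_id = row[cols["mol_id"]].strip()
            if mol_id in seen:
                raise CompoundTableError(f"{path.name} row {row_no}: duplicate mol_id {mol_id!r} within herb {herb!r}")
            seen.add(mol_id)
            compounds.append(Compound(mol_id=mol_id, name=row[cols["name"]].strip(), ob=ob, dl=dl, herb=herb))
    return compounds


def load_packaged_herb(herb: str) -> list[Compound]:
    """Load one of the packaged herb tables (``kushen`` or ``baituling``)."""
    fname = {"kushen": "kushen_components.tsv", "baituling": "baituling_components.tsv"}.get(herb)
    if fname is None:
        raise ValueError(f"unknown packaged herb {herb!r}; expected 'kushen' or 'baituling'")
    with resources.as_file(resources.files("herbnet.data").joinpath(fname)) as p:
        return read_compound_table(p, herb=herb)


def filter_compounds(
    compounds: Iterable[Compound], thresholds: AdmeThresholds = AdmeThresholds()
) -> list[Compound]:
    """Keep compounds with ob >= ob_min AND dl >= dl_min (inclusive bounds).

    Order is preserved; records duplicated across herbs are retained once per
    herb row — molecule-level de-duplication happens only at target mapping.
    """
    return [c for c in compounds if c.ob >= thresholds.ob_min and c.dl >= thresholds.dl_min]


def write_compound_table(compounds: Sequence[Compound], path: str | Path, delimiter: str = "\t") -> None:
    """Write compounds in the input tabular format plus a ``herb`` column."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(["MOLID", "molecule_name", "OB", "DL", "herb"])
        for c in compounds:
            w.writerow([c.mol_id, c.name, c.ob, c.dl, c.herb])
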