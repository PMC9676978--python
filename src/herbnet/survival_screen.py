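"""Batch prognostic screening by Kaplan-Meier median-split log-rank tests.

Each candidate gene's expression dichotomizes the cohort at its median
(ties to the low group — the dominant convention for TCGA-style KM screens),
the two groups are compared with the standard two-group log-rank test, and
genes with p below the screening threshold are reported.  The product-limit
estimator and the O/E/V log-rank accumulation are implemented directly; both
are cross-checked against an independent survival library in the test suite.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .geneset_ops import GeneSet

__all__ = [
    "SurvivalCohort",
    "GeneSurvivalResult",
    "ScreenOutput",
    "DegenerateSplitError",
    "median_split",
    "km_estimate",
    "logrank_test",
    "survival_screen",
]

logger = logging.getLogger(__name__)


class DegenerateSplitError(ValueError):
    """Median split produced an empty group (no expression variation)."""


@dataclass(frozen=True)
class SurvivalCohort:
    """Clinical follow-up plus a patient x gene expression matrix.

    ``clinical`` columns: patient_id, time (days, >= 0), event (1 = death
    observed, 0 = right-censored).  ``expression`` is indexed by patient_id.
    """

    clinical: pd.DataFrame
    expression: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"patient_id", "time", "event"}
        if not req <= set(self.clinical.columns):
            raise ValueError(f"clinical table needs columns {sorted(req)}")
        if (self.clinical["time"] < 0).any():
            raise ValueError("follow-up times must be nonnegative")
        if not self.clinical["event"].isin([0, 1]).all():
            raise ValueError("event flags must be 0/1")
        missing = set(self.clinical["patient_id"]) - set(self.expression.index)
        if missing:
            raise ValueError(f"patients missing from expression matrix: {sorted(missing)[:5]}")

    @property
    def n_patients(self) -> int:
        return len(self.clinical)

    @classmethod
    def read(cls, clinical_path: str | Path, expression_path: str | Path) -> "SurvivalCohort":
        clin = pd.read_csv(clinical_path, sep="\t")
        expr = pd.read_csv(expression_path, sep="\t", index_col=0)
        expr.columns = [c.upper() for c in expr.columns]
        return cls(clin, expr)


@dataclass(frozen=True)
class GeneSurvivalResult:
    gene: str
    n_low: int
    n_high: int
    chi2: float
    p: float


@dataclass(frozen=True)
class ScreenOutput:
    """Genes passing the threshold, the full unfiltered table, and skipped genes."""

    passing: tuple[GeneSurvivalResult, ...]
    table: pd.DataFrame
    skipped: tuple[str, ...]


def median_split(values: Sequence[float]) -> np.ndarray:
    """Boolean high-expression mask: value > median; ties go to the low group.

    Raises :class:`DegenerateSplitError` when either group would be empty
    (constant expression, or the maximum tied with the median).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("median split needs at least 2 patients")
    high = v > np.median(v)
    if not high.any() or high.all():
        raise DegenerateSplitError("median split left a group empty")
    return high


def km_estimate(times: Sequence[float], events: Sequence[int]) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns a step function as a DataFrame with columns ``time``, ``n_at_risk``,
    ``n_events`` and ``survival`` = S(t) evaluated just after each distinct
    event time: S(t) = prod_{t_i <= t} (1 - d_i / n_i).  Subjects censored at
    an event time remain at risk for that event (events processed first).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival input")
    if (t < 0).any():
        raise ValueError("times must be nonnegative")
    event_times = np.unique(t[e == 1])
    rows, s = [], 1.0
    for ti in event_times:
        n_i = int((t >= ti).sum())
        d_i = int(((t == ti) & (e == 1)).sum())
        s *= 1.0 - d_i / n_i
        rows.append((ti, n_i, d_i, s))
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def logrank_test(
    times_a: Sequence[float], events_a: Sequence[int],
    times_b: Sequence[float], events_b: Sequence[int],
) -> tuple[float, float]:
    """Two-group log-rank test.

    Accumulates, over distinct event times, group A's observed events O, its
    hypergeometric expectation E and variance V; the statistic is
    chi2 = (O - E)^2 / V, referred to a 1-df chi-square distribution.  With
    zero total events (or zero variance) returns (0, 1) by convention.
    """
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be nonempty")
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    in_a = np.zeros(t.size, dtype=bool)
    in_a[: ta.size] = True
    if e.sum() == 0:
        logger.warning("log-rank test with zero events; returning chi2=0, p=1")
        return 0.0, 1.0

    event_times = np.unique(t[e == 1])
    o_a = e_a = var = 0.0
    for ti in event_times:
        at_risk = t >= ti
        n = int(at_risk.sum())
        n_a = int((at_risk & in_a).sum())
        dying = (t == ti) & (e == 1)
        d = int(dying.sum())
        o_a += int((dying & in_a).sum())
        e_a += d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var == 0:
        logger.warning("log-rank variance is zero; returning chi2=0, p=1")
        return 0.0, 1.0
    chi2 = (o_a - e_a) ** 2 / var
    return float(chi2), float(chi2_dist.sf(chi2, df=1))


def survival_screen(
    cohort: SurvivalCohort, genes: GeneSet | Sequence[str], alpha: float = 0.05
) -> ScreenOutput:
    """Median-split log-rank screen of every gene; keep p < alpha (strict).

    Genes absent from the expression matrix, or with a degenerate median
    split, are listed in ``skipped`` rather than failing the run.  The full
    unfiltered table is returned alongside, in lexicographic gene order, so a
    stricter refinement threshold can reuse it without re-testing.
    """
    raw = genes.symbols if isinstance(genes, GeneSet) else genes
    symbols = sorted({g.upper() for g in raw})
    expr = cohort.expression.loc[cohort.clinical["patient_id"]]
    times = cohort.clinical["time"].to_numpy(float)
    events = cohort.clinical["event"].to_numpy(int)

    rows, skipped = [], []
    for gene in symbols:
        if gene not in expr.columns:
            skipped.append(gene)
            logger.warning("gene %s missing from expression matrix; skipped", gene)
            continue
        try:
            high = median_split(expr[gene].to_numpy())
        except DegenerateSplitError:
            skipped.append(gene)
            logger.warning("gene %s has a degenerate median split; skipped", gene)
            continue
        chi2, p = logrank_test(times[~high], events[~high], times[high], events[high])
        rows.append(GeneSurvivalResult(gene, int((~high).sum()), int(high.sum()), chi2, p))

    table = pd.DataFrame(
        [(r.gene, r.n_low, r.n_high, r.chi2, r.p, r.p < 0.05, r.p < 0.01) for r in rows],
        columns=["gene", "n_low", "n_high", "chi2", "p", "pass_0.05", "pass_0.01"],
    )
    passing = tuple(r for r in rows if r.p < alpha)
    return ScreenOutput(passing, table, tuple(skipped))
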