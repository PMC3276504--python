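"""Windowed overlap tests between disease and compound rankings.

For each compound, the top-k up-regulated disease genes (UC) are tested
against the compound's bottom-k genes (DB), and the bottom-k disease genes
(DC) against the compound's top-k (UB). The overlap count is scored with the
one-sided upper tail of the hypergeometric distribution — equivalently a
one-sided Fisher exact test on the 2x2 window table — and p-values are
Benjamini-Hochberg adjusted per direction across compounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from reversig.io_formats import DrugAnnotation
from reversig.ranking import RankedList, Window

logger = logging.getLogger(__name__)


class Direction(str, Enum):
    """The two reversal directions of the window comparison."""

    UC_DB = "UC_DB"  # up in cancer vs down under compound
    DC_UB = "DC_UB"  # down in cancer vs up under compound


def hypergeom_upper_tail(x: int, n_draw: int, n_success: int, n_total: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(n_total, n_success, n_draw).

    Shared by the overlap test (n_draw = n_success = k) and gene-set
    over-representation (n_draw = query size, n_success = set size).
    """
    if not 0 <= x <= min(n_draw, n_success):
        raise ValueError(f"infeasible overlap x={x} for draw={n_draw}, success={n_success}")
    if n_draw > n_total or n_success > n_total:
        raise ValueError("draw/success exceed population size")
    p = float(hypergeom.sf(x - 1, n_total, n_success, n_draw))
    # sf underflows to 0.0 for extreme overlaps; keep p in (0, 1].
    return max(p, np.finfo(float).tiny)


def overlap_pvalue(x: int, k: int, n_background: int) -> float:
    """Upper-tail probability of an overlap of x between two random k-windows.

    Equivalent to the one-sided Fisher exact test on the table
    [[x, k-x], [k-x, N-2k+x]] over a background of N genes.
    """
    if 2 * k > n_background:
        raise ValueError(f"2k={2 * k} exceeds background N={n_background}")
    return hypergeom_upper_tail(x, k, k, n_background)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class OverlapTest:
    """One compound x one direction x one window."""

    compound: str
    direction: Direction
    k: int
    overlap: int
    background: int
    p_value: float
    q_value: float = float("nan")
    significant: bool = False
    overlap_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not 0 <= self.overlap <= self.k:
            raise ValueError("overlap count outside [0, k]")
        if 2 * self.k > self.background:
            raise ValueError("2k exceeds background")


@dataclass
class CandidateRow:
    compound: str
    significant_in_UC_DB: bool
    significant_in_DC_UB: bool
    best_q: float
    annotation: DrugAnnotation | None = None

    @property
    def duality(self) -> bool:
        return self.significant_in_UC_DB and self.significant_in_DC_UB


@dataclass
class CandidateTable:
    """Merged significant calls from the two directions."""

    rows: list[CandidateRow]

    def __post_init__(self) -> None:
        names = [r.compound for r in self.rows]
        if len(set(names)) != len(names):
            raise ValueError("duplicate compounds in candidate table")
        if any(not (r.significant_in_UC_DB or r.significant_in_DC_UB) for r in self.rows):
            raise ValueError("candidate rows must be significant in at least one direction")

    @property
    def compounds(self) -> list[str]:
        return [r.compound for r in self.rows]

    def summary(self, target_disease: str | None = None) -> dict[str, object]:
        """Bookkeeping counts: per-direction totals, distinct, duality, FDA subsets."""
        ucdb = {r.compound for r in self.rows if r.significant_in_UC_DB}
        dcub = {r.compound for r in self.rows if r.significant_in_DC_UB}
        dual = {r.compound for r in self.rows if r.duality}
        fda = {
            r.compound for r in self.rows if r.annotation and r.annotation.fda_approved
        }
        recovered: set[str] = set()
        if target_disease is not None:
            target = target_disease.strip().lower()
            recovered = {
                r.compound
                for r in self.rows
                if r.annotation and target in r.annotation.approved_indications
            }
        return {
            "n_UC_DB": len(ucdb),
            "n_DC_UB": len(dcub),
            "n_distinct": len(self.rows),
            "n_duality": len(dual),
            "n_fda_approved": len(fda),
            "recovered_drugs": sorted(recovered),
            "n_recovered": len(recovered),
        }

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for r in sorted(self.rows, key=lambda r: (r.best_q, r.compound)):
            ann = r.annotation
            recs.append(
                {
                    "compound": r.compound,
                    "UC_DB": int(r.significant_in_UC_DB),
                    "DC_UB": int(r.significant_in_DC_UB),
                    "duality": int(r.duality),
                    "best_q": r.best_q,
                    "fda_approved": int(bool(ann and ann.fda_approved)),
                    "approved_indications": ";".join(sorted(ann.approved_indications))
                    if ann
                    else "",
                }
            )
        return pd.DataFrame(
            recs,
            columns=[
                "compound",
                "UC_DB",
                "DC_UB",
                "duality",
                "best_q",
                "fda_approved",
                "approved_indications",
            ],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def _direction_tests(
    disease: RankedList,
    compounds: Mapping[str, RankedList],
    direction: Direction,
    w: Window,
    fdr: float,
) -> list[OverlapTest]:
    n = disease.n_genes
    w.validate(n)
    if direction is Direction.UC_DB:
        disease_window = disease.top(w.k)
    else:
        disease_window = disease.bottom(w.k)
    tests: list[OverlapTest] = []
    xs: list[int] = []
    for name in sorted(compounds):
        cl = compounds[name]
        if cl.n_genes != n or set(cl.ordered_gene_ids) != set(disease.ordered_gene_ids):
            raise ValueError(
                f"compound {name!r} is ranked over a different gene universe"
            )
        comp_window = cl.bottom(w.k) if direction is Direction.UC_DB else cl.top(w.k)
        shared = disease_window & comp_window
        xs.append(len(shared))
        tests.append(
            OverlapTest(
                compound=name,
                direction=direction,
                k=w.k,
                overlap=len(shared),
                background=n,
                p_value=1.0,  # filled below
                overlap_genes=frozenset(shared),
            )
        )
    p = np.maximum(hypergeom.sf(np.asarray(xs) - 1, n, w.k, w.k), np.finfo(float).tiny)
    q = bh_adjust(p)
    for t, pv, qv in zip(tests, p, q):
        t.p_value = float(pv)
        t.q_value = float(qv)
        t.significant = bool(qv < fdr)
    return tests


def test_all_compounds(
    disease: RankedList,
    compounds: Mapping[str, RankedList],
    w_ucdb: Window,
    w_dcub: Window,
    fdr: float = 0.01,
) -> list[OverlapTest]:
    """Run both directional window tests for every compound.

    BH adjustment is applied separately within each direction, across
    compounds, at that direction's window size. Significance is q < ``fdr``.
    """
    tests = _direction_tests(disease, compounds, Direction.UC_DB, w_ucdb, fdr)
    tests += _direction_tests(disease, compounds, Direction.DC_UB, w_dcub, fdr)
    return tests


def significant_compounds(tests: Iterable[OverlapTest], direction: Direction) -> set[str]:
    return {t.compound for t in tests if t.direction is direction and t.significant}


def merge_candidates(
    tests: Iterable[OverlapTest],
    annotations: Mapping[str, DrugAnnotation] | None = None,
) -> CandidateTable:
    """Union the significant compounds of both directions into one table.

    A compound significant in both directions is flagged as showing duality;
    compounds significant in neither direction are excluded.
    """
    tests = list(tests)
    annotations = annotations or {}
    ucdb = significant_compounds(tests, Direction.UC_DB)
    dcub = significant_compounds(tests, Direction.DC_UB)
    best_q: dict[str, float] = {}
    for t in tests:
        if t.significant:
            best_q[t.compound] = min(best_q.get(t.compound, np.inf), t.q_value)
    rows = [
        CandidateRow(
            compound=name,
            significant_in_UC_DB=name in ucdb,
            significant_in_DC_UB=name in dcub,
            best_q=float(best_q[name]),
            annotation=annotations.get(name),
        )
        for name in sorted(ucdb | dcub)
    ]
    return CandidateTable(rows=rows)


def overlap_gene_sets(tests: Iterable[OverlapTest]) -> dict[str, frozenset[str]]:
    """Per significant compound, the union of its overlapping genes across directions."""
    out: dict[str, set[str]] = {}
    for t in tests:
        if t.significant:
            out.setdefault(t.compound, set()).update(t.overlap_genes)
    return {name: frozenset(genes) for name, genes in out.items()}


def tests_to_dataframe(tests: Iterable[OverlapTest]) -> pd.DataFrame:
    recs = [
        {
            "compound": t.compound,
            "direction": t.direction.value,
            "k": t.k,
            "overlap": t.overlap,
            "background": t.background,
            "p": t.p_value,
            "q": t.q_value,
            "significant": int(t.significant),
        }
        for t in tests
    ]
    return pd.DataFrame(
        recs,
        columns=["compound", "direction", "k", "overlap", "background", "p", "q", "significant"],
    )
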