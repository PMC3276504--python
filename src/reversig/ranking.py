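"""Ranked gene lists.

Two rankings drive the method: the disease list (genes ordered by the Welch
t-statistic of disease vs normal tissue, most up-regulated first) and one
list per compound (instance probe-ranks collapsed to genes, averaged across
the compound's instances in the matched cell line, re-ranked). Both are
total orderings over the retained common-gene universe; the k most extreme
genes at either end form the UC/DC and UB/DB windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from reversig.io_formats import (
    DISEASE,
    NORMAL,
    ExpressionMatrix,
    InstanceRankMatrix,
    canonical_compound,
)

logger = logging.getLogger(__name__)


class NoInstancesError(ValueError):
    """Raised when a compound has no instance in the requested cell line."""


@dataclass(frozen=True)
class Window:
    """Number of genes taken from each extreme of a ranked list."""

    k: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("window size k must be >= 1")

    def validate(self, n_genes: int) -> None:
        if 2 * self.k > n_genes:
            raise ValueError(
                f"window k={self.k} too large for list of {n_genes} genes "
                "(top and bottom windows must not overlap)"
            )


@dataclass
class RankedList:
    """Total ordering of gene ids by a signed score (index 0 = most up-regulated).

    Ordering is non-increasing in score; ties are broken by ascending gene id
    so that runs are bit-reproducible.
    """

    ordered_gene_ids: list[str]
    scores: dict[str, float] = field(repr=False)

    def __post_init__(self) -> None:
        if set(self.ordered_gene_ids) != set(self.scores):
            raise ValueError("ordered_gene_ids must be a permutation of score keys")
        s = self.scores
        for a, b in zip(self.ordered_gene_ids, self.ordered_gene_ids[1:]):
            if s[a] < s[b]:
                raise ValueError("ordering is not non-increasing in score")

    @classmethod
    def from_scores(cls, scores: Mapping[str, float]) -> "RankedList":
        ordered = sorted(scores, key=lambda g: (-scores[g], g))
        return cls(ordered_gene_ids=ordered, scores=dict(scores))

    @property
    def n_genes(self) -> int:
        return len(self.ordered_gene_ids)

    def top(self, k: int) -> frozenset[str]:
        return frozenset(self.ordered_gene_ids[:k])

    def bottom(self, k: int) -> frozenset[str]:
        return frozenset(self.ordered_gene_ids[-k:])

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "rank": np.arange(1, self.n_genes + 1),
                "gene": self.ordered_gene_ids,
                "score": [self.scores[g] for g in self.ordered_gene_ids],
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RankedList":
        df = pd.read_csv(path, sep="\t", dtype={"gene": str})
        return cls(
            ordered_gene_ids=list(df["gene"]),
            scores=dict(zip(df["gene"], df["score"].astype(float))),
        )


def slice_window(ranked: RankedList, w: Window) -> tuple[frozenset[str], frozenset[str]]:
    """Top-k and bottom-k gene sets of a ranked list; always disjoint."""
    w.validate(ranked.n_genes)
    return ranked.top(w.k), ranked.bottom(w.k)


def _welch_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Welch t of b minus a with a variance floor for degenerate rows."""
    na, nb = a.shape[1], b.shape[1]
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    allv = np.concatenate([va, vb])
    positive = allv[allv > 0]
    floor = float(positive.min()) if positive.size else 1.0
    n_floored = int(((va == 0) | (vb == 0)).sum())
    if n_floored:
        logger.info("rank_disease: variance floor applied to %d genes", n_floored)
    va = np.where(va > 0, va, floor)
    vb = np.where(vb > 0, vb, floor)
    return (b.mean(axis=1) - a.mean(axis=1)) / np.sqrt(va / na + vb / nb)


def rank_disease(tissue: ExpressionMatrix, retained: Iterable[str]) -> RankedList:
    """Rank genes by differential expression in disease vs normal tissue.

    Score is the per-gene Welch t-statistic (disease minus normal); the list
    is sorted descending, so index 0 is the most up-regulated gene in disease.
    """
    genes = sorted(set(retained) & set(tissue.gene_ids))
    if not genes:
        raise ValueError("no retained genes present in tissue matrix")
    sub = tissue.subset_genes(genes)
    normal = sub.values[:, sub.group_indices(NORMAL)]
    disease = sub.values[:, sub.group_indices(DISEASE)]
    if normal.shape[1] < 2 or disease.shape[1] < 2:
        raise ValueError("rank_disease needs >=2 samples in both normal and disease")
    t = _welch_t(normal, disease)
    return RankedList.from_scores(dict(zip(genes, map(float, t))))


def rank_compound(
    rm: InstanceRankMatrix,
    compound: str,
    cell_line: str,
    retained: Iterable[str],
    probe2gene: Mapping[str, str],
) -> RankedList:
    """Aggregate a compound's instances into one gene ranking.

    Per instance, probe ranks collapse to genes by the best (minimum) rank;
    gene ranks are then averaged across the compound's instances in
    ``cell_line``, restricted to the retained universe, and re-ranked. Rank 1
    (top of the list) is the gene most up-regulated by the compound, so the
    score is the negated mean rank.
    """
    instances = rm.instances_of(compound, cell_line)
    if not instances:
        raise NoInstancesError(
            f"compound {canonical_compound(compound)!r} has no instance "
            f"in cell line {cell_line!r}"
        )
    retained_set = set(retained)
    col_index = {inst: j for j, inst in enumerate(rm.instance_ids)}
    cols = [col_index[i] for i in instances]

    pairs = [
        (g, i)
        for i, p in enumerate(rm.probe_ids)
        if (g := probe2gene.get(p)) is not None and g in retained_set
    ]
    if not pairs:
        raise ValueError("no rank-matrix probes map into the retained universe")
    genes_sorted = sorted({g for g, _ in pairs})
    gidx = {g: j for j, g in enumerate(genes_sorted)}
    rows = np.fromiter((i for _, i in pairs), dtype=int, count=len(pairs))
    codes = np.fromiter((gidx[g] for g, _ in pairs), dtype=int, count=len(pairs))

    sub = rm.ranks[np.ix_(rows, np.asarray(cols, dtype=int))]
    best = np.full((len(genes_sorted), len(cols)), rm.n_probes + 1, dtype=int)
    np.minimum.at(best, codes, sub)
    mean = best.mean(axis=1)
    return RankedList.from_scores({g: -float(m) for g, m in zip(genes_sorted, mean)})


def rank_all_compounds(
    rm: InstanceRankMatrix,
    cell_line: str,
    retained: Iterable[str],
    probe2gene: Mapping[str, str],
    compounds: Sequence[str] | None = None,
) -> dict[str, RankedList]:
    """Rank every compound with at least one instance in ``cell_line``.

    Compounds without a usable instance are skipped with a logged reason;
    this is what makes the usable-compound total cell-line dependent.
    """
    names = sorted(set(compounds) if compounds is not None else rm.compounds())
    out: dict[str, RankedList] = {}
    for name in names:
        try:
            out[name] = rank_compound(rm, name, cell_line, retained, probe2gene)
        except NoInstancesError as exc:
            logger.info("skipping compound: %s", exc)
    logger.info(
        "rank_all_compounds: %d of %d compounds usable in cell line %r",
        len(out),
        len(names),
        cell_line,
    )
    return out


#: Default disease → cell line pairing used when none is configured.
DEFAULT_CELL_LINES = {
    "breast cancer": "MCF7",
    "myelogenous leukemia": "HL60",
    "prostate cancer": "PC3",
}
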