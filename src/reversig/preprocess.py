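"""Cross-platform preprocessing.

Brings the cell-line and tissue expression matrices onto a comparable scale
(per-gene z-scores against each dataset's reference samples), collapses
probes to genes, and removes genes whose baseline expression differs between
the untreated cell line and the disease tissue (two-sample Welch t-test,
Benjamini-Hochberg FDR).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from reversig.io_formats import (
    DISEASE,
    NORMAL,
    UNTREATED_CONTROL,
    ExpressionMatrix,
)
from reversig.overlap import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Outcome of the cross-platform gene filter."""

    n_input_genes: int
    n_retained: int
    removed_gene_ids: set[str]
    per_gene: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_retained != self.n_input_genes - len(self.removed_gene_ids):
            raise ValueError("retained count inconsistent with removed set")

    @property
    def fraction_retained(self) -> float:
        return self.n_retained / self.n_input_genes if self.n_input_genes else 0.0

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "gene": g,
                "t": rec["t_stat"],
                "p": rec["p_value"],
                "q": rec["q_value"],
                "removed": int(g in self.removed_gene_ids),
            }
            for g, rec in sorted(self.per_gene.items())
        ]
        return pd.DataFrame(rows, columns=["gene", "t", "p", "q", "removed"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def impute_missing(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Replace NaN entries by the row median within the sample's group."""
    if not np.isnan(matrix.values).any():
        return matrix
    values = matrix.values.copy()
    for group in matrix.groups_present():
        cols = matrix.group_indices(group)
        block = values[:, cols]
        if not np.isnan(block).any():
            continue
        med = np.nanmedian(block, axis=1, keepdims=True)
        values[:, cols] = np.where(np.isnan(block), med, block)
    return ExpressionMatrix(
        gene_ids=list(matrix.gene_ids),
        sample_ids=list(matrix.sample_ids),
        values=values,
        sample_groups=dict(matrix.sample_groups),
        dataset_id=matrix.dataset_id,
    )


def _reference_group(matrix: ExpressionMatrix) -> str:
    present = matrix.groups_present()
    if UNTREATED_CONTROL in present:
        return UNTREATED_CONTROL
    if NORMAL in present:
        return NORMAL
    raise ValueError(
        "no reference samples: matrix has neither untreated_control nor normal "
        f"groups (present: {sorted(present)})"
    )


def normalize(
    matrix: ExpressionMatrix, reference_group: str | None = None
) -> ExpressionMatrix:
    """Center and scale each gene row by its reference-sample mean and SD.

    The reference is the dataset's baseline: ``untreated_control`` for the
    cell-line matrix, ``normal`` for the tissue matrix (auto-detected when
    ``reference_group`` is None). Rows whose reference SD is zero are scaled
    by the dataset-wide median of the positive reference SDs instead, so the
    transform is defined everywhere. Population (ddof=0) SD is used.
    """
    if matrix.n_samples < 2:
        raise ValueError("normalize requires at least 2 samples")
    matrix = impute_missing(matrix)
    ref = reference_group or _reference_group(matrix)
    cols = matrix.group_indices(ref)
    if cols.size == 0:
        raise ValueError(f"no reference samples with group {ref!r}")
    ref_block = matrix.values[:, cols]
    mean = ref_block.mean(axis=1, keepdims=True)
    sd = ref_block.std(axis=1, ddof=0, keepdims=True)
    positive = sd[sd > 0]
    fallback = float(np.median(positive)) if positive.size else 1.0
    n_zero = int((sd == 0).sum())
    if n_zero:
        logger.info("normalize: %d zero-variance reference rows scaled by median SD", n_zero)
    sd = np.where(sd > 0, sd, fallback)
    return ExpressionMatrix(
        gene_ids=list(matrix.gene_ids),
        sample_ids=list(matrix.sample_ids),
        values=(matrix.values - mean) / sd,
        sample_groups=dict(matrix.sample_groups),
        dataset_id=matrix.dataset_id,
    )


def collapse_probes(
    matrix: ExpressionMatrix, probe2gene: Mapping[str, str]
) -> ExpressionMatrix:
    """Collapse probes to genes, keeping the probe with highest overall mean.

    Unmapped probes are dropped (count logged). Ties on the mean are broken by
    the lexicographically smallest probe id for reproducibility.
    """
    means = matrix.values.mean(axis=1)
    best: dict[str, tuple[float, str, int]] = {}
    n_unmapped = 0
    for i, probe in enumerate(matrix.gene_ids):
        gene = probe2gene.get(probe)
        if gene is None:
            n_unmapped += 1
            continue
        cand = (-means[i], probe, i)
        if gene not in best or cand < best[gene]:
            best[gene] = cand
    if n_unmapped:
        logger.info("collapse_probes: dropped %d unmapped probes", n_unmapped)
    if not best:
        raise ValueError("no probes map to genes")
    genes = sorted(best)
    rows = [best[g][2] for g in genes]
    return ExpressionMatrix(
        gene_ids=genes,
        sample_ids=list(matrix.sample_ids),
        values=matrix.values[rows, :],
        sample_groups=dict(matrix.sample_groups),
        dataset_id=matrix.dataset_id,
    )


def filter_common_genes(
    cellline: ExpressionMatrix,
    tissue: ExpressionMatrix,
    fdr_threshold: float = 0.01,
) -> tuple[list[str], FilterReport]:
    """Remove genes whose baseline differs between cell line and disease tissue.

    Both matrices must already be normalized and gene-collapsed. For every
    gene in the intersection of the two platforms, a two-sided Welch t-test
    compares the cell line's untreated_control samples against the tissue's
    disease samples; p-values are BH-adjusted across genes, and genes with
    q < ``fdr_threshold`` are removed. Returns the retained gene ids (sorted)
    and a full per-gene report.
    """
    common = sorted(set(cellline.gene_ids) & set(tissue.gene_ids))
    if not common:
        raise ValueError("no genes shared between the two platforms")
    a = cellline.subset_genes(common).values[:, cellline.group_indices(UNTREATED_CONTROL)]
    b = tissue.subset_genes(common).values[:, tissue.group_indices(DISEASE)]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError(
            f"need >=2 samples on each side (got {a.shape[1]} untreated_control, "
            f"{b.shape[1]} disease)"
        )
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    # Degenerate rows (zero variance on both sides) yield NaN: identical
    # constants are indistinguishable (p=1), different constants are removed.
    nan = np.isnan(p)
    if nan.any():
        equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p = np.where(nan, np.where(equal_means, 1.0, np.finfo(float).tiny), p)
        t = np.where(np.isnan(t), 0.0, t)
        logger.info("filter_common_genes: %d degenerate zero-variance genes", int(nan.sum()))
    q = bh_adjust(p)
    removed = {g for g, qv in zip(common, q) if qv < fdr_threshold}
    retained = [g for g in common if g not in removed]
    report = FilterReport(
        n_input_genes=len(common),
        n_retained=len(retained),
        removed_gene_ids=removed,
        per_gene={
            g: {"t_stat": float(tv), "p_value": float(pv), "q_value": float(qv)}
            for g, tv, pv, qv in zip(common, t, p, q)
        },
    )
    logger.info(
        "filter_common_genes: retained %d of %d genes (%.1f%%) at FDR %g",
        report.n_retained,
        report.n_input_genes,
        100 * report.fraction_retained,
        fdr_threshold,
    )
    return retained, report
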