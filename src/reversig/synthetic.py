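"""Self-contained synthetic fixtures.

Generates a normal/disease tissue cohort with planted differentially
expressed genes, an untreated cell-line baseline, a bank of compound rank
lists (most random, some constructed to mirror the reversed disease ranking
with tunable noise), drug annotations marking planted positives/negatives,
and a gene-set collection with one planted pathway plus decoys. All outputs
use exactly the dialects of :mod:`reversig.io_formats`, so every pipeline
stage runs with no download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from reversig.io_formats import (
    DISEASE,
    NORMAL,
    UNTREATED_CONTROL,
    DrugAnnotation,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    InstanceAnnotation,
    InstanceRankMatrix,
)
from reversig.io_formats import (
    write_drug_annotations,
    write_gds,
    write_gmt,
    write_rank_matrix,
)
from reversig.ranking import RankedList, rank_disease

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "simulate_tissue",
    "simulate_cellline",
    "simulate_compound_bank",
    "simulate_annotations",
    "simulate_dataset",
    "write_dataset",
    "write_gds",
    "write_rank_matrix",
    "write_gmt",
    "write_drug_annotations",
]

# Independent rng streams per generator stage, all keyed on cfg.seed.
_STREAM_BASELINE = 0
_STREAM_TISSUE = 1
_STREAM_CELLLINE = 2
_STREAM_BANK = 3
_STREAM_ANNOT = 4


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 2000
    n_normal: int = 6
    n_disease: int = 6
    n_control_instances: int = 6
    n_compounds: int = 50
    n_planted_reversers: int = 1
    reversal_noise: float = 0.1
    de_fraction: float = 0.1
    effect_size: float = 2.0
    seed: int = 0
    # instances per compound drawn uniformly from [min_instances, max_instances]
    min_instances: int = 1
    max_instances: int = 3
    # genes with "clearly different" expression between the untreated cell
    # line and disease tissue after normalization (cross-platform filter targets)
    filter_shift_fraction: float = 0.05
    filter_effect_size: float = 8.0
    # annotations
    n_failed_negatives: int = 2
    target_disease: str = "synthetic carcinoma"
    cell_line: str = "SYN1"
    # gene sets
    planted_set_size: int = 30
    n_decoy_sets: int = 10
    decoy_set_size: int = 30

    def __post_init__(self) -> None:
        for name in (
            "n_genes",
            "n_normal",
            "n_disease",
            "n_control_instances",
            "n_compounds",
            "min_instances",
            "max_instances",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("reversal_noise", "de_fraction", "filter_shift_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_planted_reversers < 0 or self.n_planted_reversers > self.n_compounds:
            raise ValueError("n_planted_reversers must lie in [0, n_compounds]")
        if self.min_instances > self.max_instances:
            raise ValueError("min_instances > max_instances")


@dataclass
class SyntheticTruth:
    """Planted structure behind one simulated dataset."""

    de_genes: dict[str, int] = field(default_factory=dict)  # gene -> shift sign
    filter_target_genes: frozenset[str] = frozenset()
    planted_compounds: frozenset[str] = frozenset()
    positives: frozenset[str] = frozenset()
    negatives: frozenset[str] = frozenset()
    planted_set_id: str | None = None


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"g{i:0{width}d}" for i in range(n)]


def _baseline(cfg: SimulationConfig) -> np.ndarray:
    rng = np.random.default_rng([cfg.seed, _STREAM_BASELINE])
    return rng.normal(0.0, 1.0, cfg.n_genes)


def simulate_tissue(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, dict[str, int], frozenset[str]]:
    """Normal/disease tissue cohorts with planted differential genes.

    Every gene is unit-variance noise around its baseline. A ``de_fraction``
    of genes is shifted by ``effect_size`` standard deviations (random sign)
    in the disease samples; a disjoint ``filter_shift_fraction`` of genes is
    shifted by the much larger ``filter_effect_size`` — these are the
    "clearly different" genes the cross-platform filter is expected to
    remove. Returns the matrix, the truth table mapping each moderate
    differential gene to its shift sign, and the filter-target genes.
    """
    rng = np.random.default_rng([cfg.seed, _STREAM_TISSUE])
    genes = _gene_ids(cfg.n_genes)
    base = _baseline(cfg)
    n_samples = cfg.n_normal + cfg.n_disease
    values = base[:, None] + rng.normal(0.0, 1.0, (cfg.n_genes, n_samples))

    n_de = int(round(cfg.de_fraction * cfg.n_genes))
    n_shift = int(round(cfg.filter_shift_fraction * cfg.n_genes))
    chosen = rng.choice(cfg.n_genes, size=n_de + n_shift, replace=False)
    de_idx, shift_idx = chosen[:n_de], chosen[n_de:]
    signs = rng.choice([-1, 1], size=n_de)
    values[de_idx, cfg.n_normal :] += cfg.effect_size * signs[:, None]
    shift_signs = rng.choice([-1, 1], size=n_shift)
    values[shift_idx, cfg.n_normal :] += cfg.filter_effect_size * shift_signs[:, None]

    sample_ids = [f"N{i:03d}" for i in range(cfg.n_normal)] + [
        f"D{i:03d}" for i in range(cfg.n_disease)
    ]
    groups = {s: (NORMAL if s.startswith("N") else DISEASE) for s in sample_ids}
    matrix = ExpressionMatrix(
        gene_ids=genes,
        sample_ids=sample_ids,
        values=values,
        sample_groups=groups,
        dataset_id=f"SYN-{cfg.seed}",
    )
    truth = {genes[i]: int(s) for i, s in zip(de_idx, signs)}
    return matrix, truth, frozenset(genes[i] for i in shift_idx)


def simulate_cellline(cfg: SimulationConfig) -> ExpressionMatrix:
    """Untreated cell-line baseline sharing the tissue's gene baselines."""
    rng = np.random.default_rng([cfg.seed, _STREAM_CELLLINE])
    genes = _gene_ids(cfg.n_genes)
    base = _baseline(cfg)
    values = base[:, None] + rng.normal(0.0, 1.0, (cfg.n_genes, cfg.n_control_instances))
    sample_ids = [f"C{i:03d}" for i in range(cfg.n_control_instances)]
    return ExpressionMatrix(
        gene_ids=genes,
        sample_ids=sample_ids,
        values=values,
        sample_groups={s: UNTREATED_CONTROL for s in sample_ids},
        dataset_id=f"SYNCL-{cfg.seed}",
    )


def _noisy_reversal(
    ordered: list[str], noise: float, rng: np.random.Generator
) -> list[str]:
    """Shuffle a random ``noise`` fraction of positions of ``ordered``."""
    out = list(ordered)
    m = int(round(noise * len(out)))
    if m >= 2:
        pos = rng.choice(len(out), size=m, replace=False)
        vals = [out[i] for i in pos]
        perm = rng.permutation(m)
        for i, j in zip(pos, perm):
            out[i] = vals[j]
    return out


def _planted_order(
    disease: RankedList, all_genes: list[str], rng: np.random.Generator
) -> list[str]:
    """Reversed disease ordering with non-ranked genes inserted uniformly."""
    rev = list(reversed(disease.ordered_gene_ids))
    extras = [g for g in all_genes if g not in disease.scores]
    n = len(rev) + len(extras)
    order: list[str | None] = [None] * n
    extra_pos = set(map(int, rng.choice(n, size=len(extras), replace=False)))
    it = iter(rev)
    for i in range(n):
        if i not in extra_pos:
            order[i] = next(it)
    for i, g in zip(sorted(extra_pos), extras):
        order[i] = g
    return order  # type: ignore[return-value]


def simulate_compound_bank(
    cfg: SimulationConfig, disease_ranking: RankedList
) -> tuple[InstanceRankMatrix, frozenset[str]]:
    """Bank of per-instance probe rank lists plus planted-reverser labels.

    ``n_planted_reversers`` compounds receive the reversed disease ordering
    with a ``reversal_noise`` fraction of positions shuffled (independently
    per instance); the rest receive independent uniform permutations. Each
    compound gets 1-3 instances. Probe ids coincide with gene ids, so the
    identity map serves as probe2gene.
    """
    rng = np.random.default_rng([cfg.seed, _STREAM_BANK])
    genes = _gene_ids(cfg.n_genes)
    n = cfg.n_genes

    width = max(3, len(str(cfg.n_compounds - 1)))
    names = [f"cmpd-{i:0{width}d}" for i in range(cfg.n_compounds)]
    planted_idx = rng.choice(cfg.n_compounds, size=cfg.n_planted_reversers, replace=False)
    planted = frozenset(names[i] for i in planted_idx)

    columns: list[np.ndarray] = []
    instance_ids: list[str] = []
    annotations: dict[str, InstanceAnnotation] = {}
    gene_index = {g: i for i, g in enumerate(genes)}
    counter = 0
    for name in names:
        n_inst = int(rng.integers(cfg.min_instances, cfg.max_instances + 1))
        for b in range(n_inst):
            inst = f"inst-{counter:04d}"
            counter += 1
            if name in planted:
                order = _noisy_reversal(
                    _planted_order(disease_ranking, genes, rng), cfg.reversal_noise, rng
                )
                ranks = np.empty(n, dtype=int)
                for pos, g in enumerate(order):
                    ranks[gene_index[g]] = pos + 1
            else:
                ranks = rng.permutation(n) + 1
            columns.append(ranks)
            instance_ids.append(inst)
            annotations[inst] = InstanceAnnotation(
                compound_name=name,
                cell_line=cfg.cell_line,
                dose="10uM",
                batch=str(b + 1),
            )

    rm = InstanceRankMatrix(
        probe_ids=genes,
        instance_ids=instance_ids,
        ranks=np.column_stack(columns),
        annotations=annotations,
    )
    return rm, planted


def simulate_annotations(
    cfg: SimulationConfig, truth: SyntheticTruth
) -> tuple[list[DrugAnnotation], GeneSetCollection, SyntheticTruth]:
    """Drug annotations and gene sets wired to the planted truth.

    One planted reverser is marked FDA-approved for the target disease (the
    positive); ``n_failed_negatives`` non-reversers are marked as having
    failed trials for it. The gene-set collection holds one planted pathway
    drawn from true differential genes plus uniform decoy sets.
    """
    rng = np.random.default_rng([cfg.seed, _STREAM_ANNOT])
    genes = _gene_ids(cfg.n_genes)
    width = max(3, len(str(cfg.n_compounds - 1)))
    names = [f"cmpd-{i:0{width}d}" for i in range(cfg.n_compounds)]

    planted_sorted = sorted(truth.planted_compounds)
    positives = frozenset(planted_sorted[:1])
    non_planted = [n for n in names if n not in truth.planted_compounds]
    neg_count = min(cfg.n_failed_negatives, len(non_planted))
    neg_idx = rng.choice(len(non_planted), size=neg_count, replace=False)
    negatives = frozenset(non_planted[i] for i in neg_idx)

    annotations = []
    for name in names:
        ann = DrugAnnotation(compound_name=name)
        if name in positives:
            ann.fda_approved = True
            ann.approved_indications = {cfg.target_disease.lower()}
        elif name in negatives:
            ann.failed_trial_indications = {cfg.target_disease.lower()}
        elif rng.random() < 0.3:
            ann.fda_approved = True
            ann.approved_indications = {"other disease"}
        annotations.append(ann)

    de_list = sorted(truth.de_genes)
    size = min(cfg.planted_set_size, len(de_list)) or 1
    members = (
        frozenset(de_list[i] for i in rng.choice(len(de_list), size=size, replace=False))
        if de_list
        else frozenset(genes[:size])
    )
    sets = {"path-planted": GeneSet("path-planted", "planted pathway", members)}
    for i in range(cfg.n_decoy_sets):
        sid = f"path-decoy{i:02d}"
        idx = rng.choice(cfg.n_genes, size=cfg.decoy_set_size, replace=False)
        sets[sid] = GeneSet(sid, f"decoy set {i}", frozenset(genes[j] for j in idx))
    collection = GeneSetCollection(sets=sets, universe_size=cfg.n_genes)

    truth = SyntheticTruth(
        de_genes=dict(truth.de_genes),
        filter_target_genes=truth.filter_target_genes,
        planted_compounds=truth.planted_compounds,
        positives=positives,
        negatives=negatives,
        planted_set_id="path-planted",
    )
    return annotations, collection, truth


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    tissue: ExpressionMatrix
    cellline: ExpressionMatrix
    bank: InstanceRankMatrix
    annotations: list[DrugAnnotation]
    gene_sets: GeneSetCollection
    truth: SyntheticTruth

    @property
    def probe2gene(self) -> dict[str, str]:
        return {p: p for p in self.bank.probe_ids}


def simulate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Generate every input the pipeline needs, wired to one seed."""
    tissue, de_truth, filter_targets = simulate_tissue(cfg)
    cellline = simulate_cellline(cfg)
    disease_ranking = rank_disease(tissue, tissue.gene_ids)
    bank, planted = simulate_compound_bank(cfg, disease_ranking)
    truth = SyntheticTruth(
        de_genes=de_truth, filter_target_genes=filter_targets, planted_compounds=planted
    )
    annotations, gene_sets, truth = simulate_annotations(cfg, truth)
    return SyntheticDataset(
        config=cfg,
        tissue=tissue,
        cellline=cellline,
        bank=bank,
        annotations=annotations,
        gene_sets=gene_sets,
        truth=truth,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every input file in the io_formats dialects; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tissue": outdir / "tissue.gds.tsv",
        "cellline": outdir / "cellline.gds.tsv",
        "rank_matrix": outdir / "bank.ranks.tsv",
        "rank_annotations": outdir / "bank.instances.tsv",
        "drug_annotations": outdir / "drugs.tsv",
        "gene_sets": outdir / "genesets.gmt",
        "truth": outdir / "truth.tsv",
    }
    write_gds(ds.tissue, paths["tissue"])
    write_gds(ds.cellline, paths["cellline"])
    write_rank_matrix(ds.bank, paths["rank_matrix"], paths["rank_annotations"])
    write_drug_annotations(ds.annotations, paths["drug_annotations"])
    write_gmt(ds.gene_sets, paths["gene_sets"])

    lines = [f"# seed = {ds.config.seed}", "kind\tid\tvalue"]
    for g in sorted(ds.truth.de_genes):
        lines.append(f"de_gene\t{g}\t{ds.truth.de_genes[g]}")
    for g in sorted(ds.truth.filter_target_genes):
        lines.append(f"filter_target\t{g}\t")
    for c in sorted(ds.truth.planted_compounds):
        lines.append(f"planted_reverser\t{c}\t")
    for c in sorted(ds.truth.positives):
        lines.append(f"positive\t{c}\t")
    for c in sorted(ds.truth.negatives):
        lines.append(f"negative\t{c}\t")
    if ds.truth.planted_set_id:
        lines.append(f"planted_set\t{ds.truth.planted_set_id}\t")
    paths["truth"].write_text("\n".join(lines) + "\n")
    return paths
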