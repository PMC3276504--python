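"""Domain types and file formats.

Every external format the pipeline touches is read and written here; all
downstream modules consume only the in-memory types defined in this module.

Formats
-------
- Expression tables: either a GDS/SOFT-style dump (``^DATASET``/``^SUBSET``
  metadata followed by a ``!dataset_table_begin`` block) or a plain
  tab-delimited matrix with a two-column group sidecar.
- Instance rank matrices: tab-delimited probes x instances, each column a
  permutation of 1..P, with a separate instance annotation table.
- Gene sets: standard GMT.
- Drug annotations: tab-delimited with boolean and semicolon-separated
  list-valued columns.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Canonical sample group labels.
NORMAL = "normal"
DISEASE = "disease"
UNTREATED_CONTROL = "untreated_control"
TREATED = "treated"
GROUP_LABELS = frozenset({NORMAL, DISEASE, UNTREATED_CONTROL, TREATED})


def canonical_compound(name: str) -> str:
    """Canonical compound name: lowercase and trimmed. No synonym resolution."""
    return name.strip().lower()


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-sample group labels.

    Values are kept in the units provided (log scale assumed, not enforced).
    Missing values are represented as NaN; imputation is a preprocessing
    concern, not an I/O one.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    sample_groups: dict[str, str]
    dataset_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        unlabeled = [s for s in self.sample_ids if s not in self.sample_groups]
        if unlabeled:
            raise ValueError(f"samples without group label: {unlabeled}")
        bad = {s: g for s, g in self.sample_groups.items() if g not in GROUP_LABELS}
        if bad:
            raise ValueError(f"unknown group labels: {bad}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def group_indices(self, group: str) -> np.ndarray:
        """Column indices of the samples carrying ``group``."""
        return np.array(
            [i for i, s in enumerate(self.sample_ids) if self.sample_groups[s] == group],
            dtype=int,
        )

    def groups_present(self) -> set[str]:
        return {self.sample_groups[s] for s in self.sample_ids}

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to ``gene_ids`` in the given order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(
            gene_ids=list(gene_ids),
            sample_ids=list(self.sample_ids),
            values=self.values[rows, :],
            sample_groups=dict(self.sample_groups),
            dataset_id=self.dataset_id,
        )


@dataclass
class InstanceAnnotation:
    compound_name: str
    cell_line: str
    dose: str = ""
    batch: str = ""


@dataclass
class InstanceRankMatrix:
    """Per-instance probe rank lists (each column a permutation of 1..P)."""

    probe_ids: list[str]
    instance_ids: list[str]
    ranks: np.ndarray
    annotations: dict[str, InstanceAnnotation]

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, dtype=int)
        p = len(self.probe_ids)
        if self.ranks.shape != (p, len(self.instance_ids)):
            raise ValueError(
                f"rank matrix shape {self.ranks.shape} does not match "
                f"{p} probes x {len(self.instance_ids)} instances"
            )
        expected = np.arange(1, p + 1)
        for j, inst in enumerate(self.instance_ids):
            col = np.sort(self.ranks[:, j])
            if not np.array_equal(col, expected):
                raise ValueError(
                    f"instance {inst!r}: column is not a permutation of 1..{p}"
                )
        for inst in self.instance_ids:
            ann = self.annotations.get(inst)
            if ann is None:
                raise ValueError(f"instance {inst!r} lacks an annotation")
            if not ann.compound_name or not ann.cell_line:
                raise ValueError(
                    f"instance {inst!r}: annotation needs compound_name and cell_line"
                )

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    def compounds(self) -> set[str]:
        return {
            canonical_compound(self.annotations[i].compound_name)
            for i in self.instance_ids
        }

    def instances_of(self, compound: str, cell_line: str | None = None) -> list[str]:
        """Instance ids of ``compound`` (canonical match), optionally per cell line."""
        want = canonical_compound(compound)
        out = []
        for inst in self.instance_ids:
            ann = self.annotations[inst]
            if canonical_compound(ann.compound_name) != want:
                continue
            if cell_line is not None and ann.cell_line != cell_line:
                continue
            out.append(inst)
        return out


@dataclass
class DrugAnnotation:
    """FDA status and indication sets for one compound (canonical name)."""

    compound_name: str
    fda_approved: bool = False
    approved_indications: set[str] = field(default_factory=set)
    failed_trial_indications: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.compound_name = canonical_compound(self.compound_name)
        if not self.compound_name:
            raise ValueError("compound_name must be non-empty")


@dataclass
class GeneSet:
    set_id: str
    name: str
    members: frozenset[str]


@dataclass
class GeneSetCollection:
    sets: dict[str, GeneSet]
    universe_size: int | None = None

    def __post_init__(self) -> None:
        for sid, gs in self.sets.items():
            if sid != gs.set_id:
                raise ValueError(f"set key {sid!r} != set id {gs.set_id!r}")
            if not gs.members:
                raise ValueError(f"gene set {sid!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# Expression tables (GDS/SOFT or plain matrix + sidecar)
# ---------------------------------------------------------------------------

_MISSING_TOKENS = {"", "null", "na", "nan", "none", "--"}


def _parse_value(token: str) -> float:
    token = token.strip()
    if token.lower() in _MISSING_TOKENS:
        return math.nan
    try:
        return float(token)
    except ValueError:
        return math.nan


def _read_group_sidecar(path: str | Path) -> dict[str, str]:
    groups: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"group sidecar line needs 2 fields: {line!r}")
        sample, group = parts[0].strip(), parts[1].strip()
        if sample in groups:
            raise ValueError(f"duplicate sample in group sidecar: {sample!r}")
        groups[sample] = group
    return groups


def read_gds(
    path: str | Path,
    groups: str | Path | Mapping[str, str] | None = None,
    group_map: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Read a GDS/SOFT-style table or a plain matrix into an ExpressionMatrix.

    Parameters
    ----------
    path:
        SOFT-style file (metadata lines starting with ``^``/``!``/``#`` and a
        ``!dataset_table_begin`` block) or a plain tab-delimited matrix whose
        header row holds sample ids.
    groups:
        Sample→group assignment: a mapping, or a path to a two-column
        tab-delimited sidecar. Overrides any subset metadata in the file.
        Required for plain matrices without subset metadata.
    group_map:
        Optional mapping from SOFT subset descriptions to canonical group
        labels (``normal`` / ``disease`` / ``untreated_control`` / ``treated``).

    Rows with non-numeric entries in more than 50% of samples are dropped
    (count logged); remaining non-numeric entries become NaN.
    """
    lines = Path(path).read_text().splitlines()
    is_soft = any(ln.startswith(("^", "!")) for ln in lines[:50])

    dataset_id: str | None = None
    subset_groups: dict[str, str] = {}
    if is_soft:
        table_lines: list[str] = []
        in_table = False
        current_subset_samples: list[str] = []
        current_subset_desc: str | None = None

        def flush_subset() -> None:
            nonlocal current_subset_samples, current_subset_desc
            if current_subset_samples and current_subset_desc is not None:
                desc = current_subset_desc.strip()
                label = (group_map or {}).get(desc, desc)
                for s in current_subset_samples:
                    subset_groups[s] = label
            current_subset_samples = []
            current_subset_desc = None

        for ln in lines:
            if ln.startswith("!dataset_table_begin"):
                in_table = True
                continue
            if ln.startswith("!dataset_table_end"):
                in_table = False
                continue
            if in_table:
                table_lines.append(ln)
                continue
            if ln.startswith("^DATASET"):
                _, _, value = ln.partition("=")
                dataset_id = value.strip() or None
            elif ln.startswith("^SUBSET"):
                flush_subset()
            elif ln.startswith("!subset_description"):
                _, _, value = ln.partition("=")
                current_subset_desc = value
            elif ln.startswith("!subset_sample_id"):
                _, _, value = ln.partition("=")
                current_subset_samples = [s.strip() for s in value.split(",") if s.strip()]
        flush_subset()
        if not table_lines:
            raise ValueError(f"{path}: no !dataset_table_begin block found")
    else:
        table_lines = [ln for ln in lines if ln.strip() and not ln.startswith("#")]

    header = table_lines[0].rstrip("\n").split("\t")
    # SOFT tables carry ID_REF and often IDENTIFIER before the sample columns.
    n_meta = 1
    if len(header) > 2 and header[1].strip().upper() == "IDENTIFIER":
        n_meta = 2
    sample_ids = [h.strip() for h in header[n_meta:]]
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValueError(f"{path}: duplicated sample ids: {dupes}")

    gene_ids: list[str] = []
    rows: list[list[float]] = []
    n_dropped = 0
    for ln in table_lines[1:]:
        if not ln.strip():
            continue
        parts = ln.rstrip("\n").split("\t")
        gid = parts[0].strip()
        vals = [_parse_value(tok) for tok in parts[n_meta : n_meta + len(sample_ids)]]
        vals += [math.nan] * (len(sample_ids) - len(vals))
        n_missing = sum(math.isnan(v) for v in vals)
        if n_missing * 2 > len(sample_ids):
            n_dropped += 1
            continue
        gene_ids.append(gid)
        rows.append(vals)
    if n_dropped:
        logger.info("%s: dropped %d rows with >50%% non-numeric entries", path, n_dropped)

    if groups is not None:
        if isinstance(groups, (str, Path)):
            sample_groups = _read_group_sidecar(groups)
        else:
            sample_groups = dict(groups)
    else:
        sample_groups = subset_groups
    unlabeled = [s for s in sample_ids if s not in sample_groups]
    if unlabeled:
        raise ValueError(f"{path}: samples without group label: {unlabeled}")

    return ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=np.array(rows, dtype=float).reshape(len(gene_ids), len(sample_ids)),
        sample_groups={s: sample_groups[s] for s in sample_ids},
        dataset_id=dataset_id,
    )


def write_gds(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write an ExpressionMatrix as a SOFT-style GDS table (round-trips with read_gds)."""
    out: list[str] = []
    out.append(f"^DATASET = {matrix.dataset_id or ''}")
    by_group: dict[str, list[str]] = {}
    for s in matrix.sample_ids:
        by_group.setdefault(matrix.sample_groups[s], []).append(s)
    for i, (group, samples) in enumerate(sorted(by_group.items()), start=1):
        out.append(f"^SUBSET = {i}")
        out.append(f"!subset_description = {group}")
        out.append(f"!subset_sample_id = {','.join(samples)}")
    out.append("!dataset_table_begin")
    out.append("\t".join(["ID_REF"] + matrix.sample_ids))
    for gid, row in zip(matrix.gene_ids, matrix.values):
        cells = ["null" if math.isnan(v) else repr(float(v)) for v in row]
        out.append("\t".join([gid] + cells))
    out.append("!dataset_table_end")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Instance rank matrices
# ---------------------------------------------------------------------------


def read_rank_matrix(path: str | Path, annotation_path: str | Path) -> InstanceRankMatrix:
    """Read a probes x instances integer rank matrix plus its annotation table.

    Instances lacking an annotation row are dropped with a warning. A column
    that is not a permutation of 1..P is a hard error naming the instance.
    """
    annotations: dict[str, InstanceAnnotation] = {}
    ann_lines = Path(annotation_path).read_text().splitlines()
    header = ann_lines[0].rstrip("\n").split("\t")
    col = {name: i for i, name in enumerate(header)}
    for required in ("instance_id", "compound_name", "cell_line"):
        if required not in col:
            raise ValueError(f"{annotation_path}: missing column {required!r}")
    for ln in ann_lines[1:]:
        if not ln.strip():
            continue
        parts = ln.rstrip("\n").split("\t")

        def get(name: str) -> str:
            i = col.get(name)
            return parts[i].strip() if i is not None and i < len(parts) else ""

        inst = get("instance_id")
        annotations[inst] = InstanceAnnotation(
            compound_name=get("compound_name"),
            cell_line=get("cell_line"),
            dose=get("dose"),
            batch=get("batch"),
        )

    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    mat_header = lines[0].rstrip("\n").split("\t")
    instance_ids = [h.strip() for h in mat_header[1:]]
    probe_ids: list[str] = []
    rows: list[list[int]] = []
    for ln in lines[1:]:
        parts = ln.rstrip("\n").split("\t")
        probe_ids.append(parts[0].strip())
        rows.append([int(tok) for tok in parts[1:]])
    ranks = np.array(rows, dtype=int)

    keep = [j for j, inst in enumerate(instance_ids) if inst in annotations]
    dropped = [inst for inst in instance_ids if inst not in annotations]
    if dropped:
        logger.warning("%s: dropped %d unannotated instances: %s", path, len(dropped), dropped)
    kept_ids = [instance_ids[j] for j in keep]

    return InstanceRankMatrix(
        probe_ids=probe_ids,
        instance_ids=kept_ids,
        ranks=ranks[:, keep],
        annotations={i: annotations[i] for i in kept_ids},
    )


def write_rank_matrix(
    rm: InstanceRankMatrix, path: str | Path, annotation_path: str | Path
) -> None:
    lines = ["\t".join(["probe_id"] + rm.instance_ids)]
    for pid, row in zip(rm.probe_ids, rm.ranks):
        lines.append("\t".join([pid] + [str(int(v)) for v in row]))
    Path(path).write_text("\n".join(lines) + "\n")

    ann_lines = ["instance_id\tcompound_name\tcell_line\tdose\tbatch"]
    for inst in rm.instance_ids:
        a = rm.annotations[inst]
        ann_lines.append("\t".join([inst, a.compound_name, a.cell_line, a.dose, a.batch]))
    Path(annotation_path).write_text("\n".join(ann_lines) + "\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path, universe_size: int | None = None) -> GeneSetCollection:
    """Read a GMT file; lines with fewer than 3 fields are skipped with a warning."""
    sets: dict[str, GeneSet] = {}
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        if not ln.strip():
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 3:
            logger.warning("%s:%d: skipping GMT line with <3 fields", path, lineno)
            continue
        set_id, name = parts[0].strip(), parts[1].strip()
        members = frozenset(g.strip() for g in parts[2:] if g.strip())
        if not members:
            logger.warning("%s:%d: skipping GMT set %r with no members", path, lineno, set_id)
            continue
        if set_id in sets:
            raise ValueError(f"{path}: duplicate gene-set id {set_id!r}")
        sets[set_id] = GeneSet(set_id=set_id, name=name, members=members)
    if not sets:
        raise ValueError(f"{path}: no usable gene sets")
    return GeneSetCollection(sets=sets, universe_size=universe_size)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for sid in sorted(collection.sets):
        gs = collection.sets[sid]
        lines.append("\t".join([gs.set_id, gs.name] + sorted(gs.members)))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Drug annotations
# ---------------------------------------------------------------------------

_TRUE_TOKENS = {"1", "true", "yes", "y", "t"}
_FALSE_TOKENS = {"0", "false", "no", "n", "f", ""}


def _parse_bool(token: str) -> bool:
    token = token.strip().lower()
    if token in _TRUE_TOKENS:
        return True
    if token in _FALSE_TOKENS:
        return False
    raise ValueError(f"cannot parse boolean field {token!r}")


def _parse_indications(token: str) -> set[str]:
    return {t.strip().lower() for t in token.split(";") if t.strip()}


def read_drug_annotations(path: str | Path) -> list[DrugAnnotation]:
    """Read the drug annotation table.

    Columns (tab-delimited, with header): compound, fda_approved,
    approved_indications, failed_trial_indications; indication fields are
    semicolon-separated. Duplicate compound rows (case-insensitive) are merged
    with the union of their indications and OR of approval flags.
    """
    lines = Path(path).read_text().splitlines()
    merged: dict[str, DrugAnnotation] = {}
    n_merged = 0
    for ln in lines[1:]:
        if not ln.strip():
            continue
        parts = (ln.rstrip("\n").split("\t") + ["", "", ""])[:4]
        ann = DrugAnnotation(
            compound_name=parts[0],
            fda_approved=_parse_bool(parts[1]),
            approved_indications=_parse_indications(parts[2]),
            failed_trial_indications=_parse_indications(parts[3]),
        )
        prev = merged.get(ann.compound_name)
        if prev is None:
            merged[ann.compound_name] = ann
        else:
            n_merged += 1
            prev.fda_approved = prev.fda_approved or ann.fda_approved
            prev.approved_indications |= ann.approved_indications
            prev.failed_trial_indications |= ann.failed_trial_indications
    if n_merged:
        logger.info("%s: merged %d duplicate compound rows", path, n_merged)
    return [merged[name] for name in sorted(merged)]


def write_drug_annotations(annotations: Iterable[DrugAnnotation], path: str | Path) -> None:
    lines = ["compound\tfda_approved\tapproved_indications\tfailed_trial_indications"]
    for ann in sorted(annotations, key=lambda a: a.compound_name):
        lines.append(
            "\t".join(
                [
                    ann.compound_name,
                    "1" if ann.fda_approved else "0",
                    ";".join(sorted(ann.approved_indications)),
                    ";".join(sorted(ann.failed_trial_indications)),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def annotation_index(annotations: Iterable[DrugAnnotation]) -> dict[str, DrugAnnotation]:
    """Map canonical compound name → annotation."""
    return {a.compound_name: a for a in annotations}
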