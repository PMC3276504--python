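"""Window-size selection.

The window k is scanned over a grid (default 100..10000 step 100) and, per
direction, the operating k is the one with maximum specificity among those
with non-zero sensitivity (at least one known drug recovered), non-zero
duality and at least one FDR-significant discovery. Positives are compounds
FDA-approved for the target disease that are present in the compound bank;
negatives are compounds whose trials for the target disease failed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from reversig.io_formats import DrugAnnotation
from reversig.overlap import (
    Direction,
    merge_candidates,
    significant_compounds,
    test_all_compounds,
)
from reversig.ranking import RankedList, Window

logger = logging.getLogger(__name__)

#: Specificity on the failed-trial class: |negatives \ identified| / |negatives|.
SPECIFICITY_STANDARD = "standard"
#: Literal alternative: 1 - |identified ∩ negatives| / |identified|.
SPECIFICITY_IDENTIFIED = "identified"


def default_k_grid(n_genes: int | None = None) -> list[int]:
    """k = 100, 200, ..., 10000, truncated so both windows fit the universe."""
    grid = list(range(100, 10001, 100))
    if n_genes is not None:
        grid = [k for k in grid if 2 * k <= n_genes]
    return grid


def known_positives(
    annotations: Mapping[str, DrugAnnotation],
    compounds: Sequence[str],
    target_disease: str,
) -> set[str]:
    """Compounds in the bank that are FDA-approved for the target disease."""
    target = target_disease.strip().lower()
    present = set(compounds)
    return {
        name
        for name, ann in annotations.items()
        if name in present and ann.fda_approved and target in ann.approved_indications
    }


def known_negatives(
    annotations: Mapping[str, DrugAnnotation],
    compounds: Sequence[str],
    target_disease: str,
) -> set[str]:
    """Compounds in the bank whose trials for the target disease failed."""
    target = target_disease.strip().lower()
    present = set(compounds)
    return {
        name
        for name, ann in annotations.items()
        if name in present and target in ann.failed_trial_indications
    }


@dataclass
class KRecord:
    """Per-k evaluation of one direction."""

    k: int
    n_significant: int
    sensitivity: float
    specificity: float
    n_duality: int
    recovered_drugs: frozenset[str]


@dataclass
class ScanResult:
    """Per-k trace of one direction's scan plus the selected window."""

    direction: Direction
    grid: list[int]
    per_k: dict[int, KRecord]
    selected_k: int | None = None
    selection_rationale: dict[str, object] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        recs = [
            {
                "k": r.k,
                "n_significant": r.n_significant,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "n_duality": r.n_duality,
                "recovered_drugs": ";".join(sorted(r.recovered_drugs)),
            }
            for r in (self.per_k[k] for k in self.grid)
        ]
        return pd.DataFrame(
            recs,
            columns=["k", "n_significant", "sensitivity", "specificity", "n_duality", "recovered_drugs"],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, direction: Direction = Direction.UC_DB) -> "ScanResult":
        df = pd.read_csv(path, sep="\t")
        per_k = {}
        for rec in df.to_dict("records"):
            drugs = rec.get("recovered_drugs", "")
            drugs = "" if pd.isna(drugs) else str(drugs)
            per_k[int(rec["k"])] = KRecord(
                k=int(rec["k"]),
                n_significant=int(rec["n_significant"]),
                sensitivity=float(rec["sensitivity"]),
                specificity=float(rec["specificity"]),
                n_duality=int(rec["n_duality"]),
                recovered_drugs=frozenset(d for d in drugs.split(";") if d),
            )
        return cls(direction=direction, grid=sorted(per_k), per_k=per_k)


def evaluate_k(
    disease: RankedList,
    compounds: Mapping[str, RankedList],
    k: int,
    annotations: Mapping[str, DrugAnnotation],
    target_disease: str,
    direction: Direction = Direction.UC_DB,
    fdr: float = 0.01,
    specificity_mode: str = SPECIFICITY_STANDARD,
) -> KRecord:
    """Evaluate one window size for one direction.

    Both directions are tested at the same k so that duality is defined;
    sensitivity/specificity and the significant count are scored on the
    requested direction's calls.
    """
    positives = known_positives(annotations, list(compounds), target_disease)
    if not positives:
        raise ValueError(
            f"no known positives: annotate at least one compound in the bank as "
            f"FDA-approved for {target_disease!r}"
        )
    negatives = known_negatives(annotations, list(compounds), target_disease)

    w = Window(k)
    tests = test_all_compounds(disease, compounds, w, w, fdr=fdr)
    identified = significant_compounds(tests, direction)
    other = Direction.DC_UB if direction is Direction.UC_DB else Direction.UC_DB
    dual = identified & significant_compounds(tests, other)

    sensitivity = len(identified & positives) / len(positives)
    if specificity_mode == SPECIFICITY_STANDARD:
        specificity = len(negatives - identified) / len(negatives) if negatives else 1.0
    elif specificity_mode == SPECIFICITY_IDENTIFIED:
        specificity = (
            1.0 - len(identified & negatives) / len(identified) if identified else 1.0
        )
    else:
        raise ValueError(f"unknown specificity_mode {specificity_mode!r}")

    return KRecord(
        k=k,
        n_significant=len(identified),
        sensitivity=sensitivity,
        specificity=specificity,
        n_duality=len(dual),
        recovered_drugs=frozenset(identified & positives),
    )


def scan_windows(
    disease: RankedList,
    compounds: Mapping[str, RankedList],
    annotations: Mapping[str, DrugAnnotation],
    target_disease: str,
    direction: Direction = Direction.UC_DB,
    grid: Sequence[int] | None = None,
    fdr: float = 0.01,
    specificity_mode: str = SPECIFICITY_STANDARD,
) -> ScanResult:
    """Evaluate every k on the grid for one direction."""
    grid = list(grid) if grid is not None else default_k_grid(disease.n_genes)
    if not grid:
        raise ValueError("empty window grid")
    per_k = {
        k: evaluate_k(
            disease,
            compounds,
            k,
            annotations,
            target_disease,
            direction=direction,
            fdr=fdr,
            specificity_mode=specificity_mode,
        )
        for k in grid
    }
    return ScanResult(direction=direction, grid=grid, per_k=per_k)


def select_window(scan: ScanResult) -> Window:
    """Pick the operating window from a completed scan.

    Feasible k satisfy sensitivity > 0, duality > 0 and at least one
    FDR-significant discovery; among those, the smallest k of maximum
    specificity wins. Selection depends only on the scan trace, so replaying
    a serialized trace reproduces the choice.
    """
    feasible = [
        k
        for k in scan.grid
        if scan.per_k[k].sensitivity > 0
        and scan.per_k[k].n_duality > 0
        and scan.per_k[k].n_significant > 0
    ]
    if not feasible:
        diag = {
            "n_k_with_sensitivity": sum(1 for k in scan.grid if scan.per_k[k].sensitivity > 0),
            "n_k_with_duality": sum(1 for k in scan.grid if scan.per_k[k].n_duality > 0),
            "n_k_with_discoveries": sum(1 for k in scan.grid if scan.per_k[k].n_significant > 0),
        }
        raise ValueError(f"no feasible window size on the grid; constraint counts: {diag}")
    best = min(feasible, key=lambda k: (-scan.per_k[k].specificity, k))
    scan.selected_k = best
    scan.selection_rationale = {
        "feasible_k": feasible,
        "specificity_at_selected": scan.per_k[best].specificity,
        "sensitivity_at_selected": scan.per_k[best].sensitivity,
        "n_duality_at_selected": scan.per_k[best].n_duality,
    }
    logger.info(
        "select_window[%s]: k=%d (specificity %.3f, sensitivity %.3f, duality %d)",
        scan.direction.value,
        best,
        scan.per_k[best].specificity,
        scan.per_k[best].sensitivity,
        scan.per_k[best].n_duality,
    )
    return Window(best)


def plot_scan(scan: ScanResult, path: str | Path) -> None:
    """Specificity/sensitivity trace over the k grid (static PNG/PDF)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = scan.to_dataframe()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(df["k"], df["sensitivity"], marker="o", label="sensitivity")
    ax.plot(df["k"], df["specificity"], marker="s", label="specificity")
    if scan.selected_k is not None:
        ax.axvline(scan.selected_k, color="grey", linestyle="--", label=f"selected k={scan.selected_k}")
    ax.set_xlabel("window size k")
    ax.set_ylabel("fraction")
    ax.set_title(f"window scan ({scan.direction.value})")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
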