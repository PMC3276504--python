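"""Gene-set over-representation of candidate gene windows.

Query genes (the overlapping genes behind a candidate call) are scored
against each gene set with the hypergeometric upper tail over the retained
common-gene universe. Pathway mode applies a raw p < alpha cut with no
multiplicity correction; GO mode keeps only "informative" terms — sets with
more than a minimum number of annotatable genes in the universe — at a BH
FDR threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from reversig.io_formats import GeneSetCollection
from reversig.overlap import bh_adjust, hypergeom_upper_tail

logger = logging.getLogger(__name__)

PATHWAY_MODE = "pathway"
GO_MODE = "go"


@dataclass
class EnrichmentResult:
    set_id: str
    name: str
    n_hits: int
    set_size: int
    query_size: int
    universe_size: int
    p_value: float
    q_value: float | None = None

    def __post_init__(self) -> None:
        if self.n_hits > min(self.set_size, self.query_size):
            raise ValueError("hits exceed set or query size")


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    mode: str = PATHWAY_MODE,
    alpha: float = 0.05,
    go_fdr: float = 0.01,
    go_min_size: int = 400,
) -> list[EnrichmentResult]:
    """Over-representation of ``query`` genes in each set of ``collection``.

    Set members are intersected with the universe before testing; set sizes
    (including the informative-term size rule in GO mode) are counted within
    the universe. Returns only the sets passing the mode's acceptance rule,
    sorted by p-value.
    """
    universe = set(universe)
    query = set(query)
    if not query:
        raise ValueError("empty query gene set")
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    n_universe = len(universe)

    results: list[EnrichmentResult] = []
    for sid in sorted(collection.sets):
        gs = collection.sets[sid]
        members = gs.members & universe
        if not members:
            continue
        hits = len(members & query)
        p = hypergeom_upper_tail(hits, len(query), len(members), n_universe)
        results.append(
            EnrichmentResult(
                set_id=sid,
                name=gs.name,
                n_hits=hits,
                set_size=len(members),
                query_size=len(query),
                universe_size=n_universe,
                p_value=p,
            )
        )

    if mode == PATHWAY_MODE:
        kept = [r for r in results if r.p_value < alpha]
    elif mode == GO_MODE:
        q = bh_adjust([r.p_value for r in results]) if results else []
        for r, qv in zip(results, q):
            r.q_value = float(qv)
        kept = [
            r for r in results if r.q_value is not None and r.q_value < go_fdr and r.set_size > go_min_size
        ]
    else:
        raise ValueError(f"unknown enrichment mode {mode!r}")
    return sorted(kept, key=lambda r: (r.p_value, r.set_id))


def compound_pathway_matrix(
    per_compound_genes: Mapping[str, Iterable[str]],
    collection: GeneSetCollection,
    universe: Iterable[str],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.Series]:
    """Which identified compounds perturb which pathways.

    A compound perturbs a pathway when its overlapping-gene set is
    over-represented in that pathway at raw p < ``alpha``. Returns the binary
    compound x pathway matrix and the per-pathway percentage of compounds
    perturbing it (the bar-plot summary statistic).
    """
    universe = set(universe)
    compounds = sorted(per_compound_genes)
    pathways = sorted(collection.sets)
    data = pd.DataFrame(0, index=compounds, columns=pathways, dtype=int)
    for name in compounds:
        genes = set(per_compound_genes[name])
        if not genes:
            continue
        for res in enrich(genes, collection, universe, mode=PATHWAY_MODE, alpha=alpha):
            data.loc[name, res.set_id] = 1
    percent = 100.0 * data.mean(axis=0)
    percent.name = "percent_compounds"
    return data, percent


def results_to_dataframe(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    recs = [
        {
            "set_id": r.set_id,
            "name": r.name,
            "hits": r.n_hits,
            "set_size": r.set_size,
            "query_size": r.query_size,
            "universe_size": r.universe_size,
            "p": r.p_value,
            "q": "" if r.q_value is None else r.q_value,
        }
        for r in results
    ]
    return pd.DataFrame(
        recs,
        columns=["set_id", "name", "hits", "set_size", "query_size", "universe_size", "p", "q"],
    )


def write_results(results: Iterable[EnrichmentResult], path: str | Path) -> None:
    results_to_dataframe(results).to_csv(path, sep="\t", index=False)
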