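import numpy as np
import pytest

from reversig.io_formats import (
    DISEASE,
    NORMAL,
    UNTREATED_CONTROL,
    ExpressionMatrix,
    InstanceAnnotation,
    InstanceRankMatrix,
)
from reversig.ranking import RankedList
from reversig.synthetic import SimulationConfig, simulate_dataset


def make_matrix(values, groups, gene_ids=None, sample_ids=None, dataset_id=None):
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    sample_ids = sample_ids or [f"s{i}" for i in range(n_samples)]
    if isinstance(groups, (list, tuple)):
        groups = dict(zip(sample_ids, groups))
    return ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=values,
        sample_groups=groups,
        dataset_id=dataset_id,
    )


def make_ranked(ordered):
    """RankedList with the given explicit order (scores descending)."""
    n = len(ordered)
    return RankedList(
        ordered_gene_ids=list(ordered),
        scores={g: float(n - i) for i, g in enumerate(ordered)},
    )


def make_rank_matrix(columns, probe_ids=None, compounds=None, cell_line="SYN1"):
    """InstanceRankMatrix from a list of rank columns (one per instance)."""
    columns = [np.asarray(c, dtype=int) for c in columns]
    p = len(columns[0])
    probe_ids = probe_ids or [f"p{i}" for i in range(p)]
    instance_ids = [f"inst{i}" for i in range(len(columns))]
    compounds = compounds or ["drugA"] * len(columns)
    annotations = {
        inst: InstanceAnnotation(compound_name=c, cell_line=cell_line)
        for inst, c in zip(instance_ids, compounds)
    }
    return InstanceRankMatrix(
        probe_ids=probe_ids,
        instance_ids=instance_ids,
        ranks=np.column_stack(columns),
        annotations=annotations,
    )


@pytest.fixture(scope="session")
def default_dataset():
    return simulate_dataset(SimulationConfig(seed=0))


@pytest.fixture
def tiny_tissue():
    # 4 genes x (2 normal + 2 disease)
    return make_matrix(
        [[1.0, 1.0, 5.0, 5.0], [2.0, 2.0, 2.0, 2.0], [3.0, 4.0, 1.0, 0.0], [0.0, 2.0, 3.0, 3.0]],
        [NORMAL, NORMAL, DISEASE, DISEASE],
    )


collect_ignore_glob: list[str] = []
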