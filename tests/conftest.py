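import numpy as np
import pandas as pd
import pytest

from cellsort import (
    ExpressionMatrix,
    MarkerTable,
    normalize,
    normalize_and_restrict,
    synth_expression,
    synth_marker_table,
)
from cellsort.io import ClusterLabels


@pytest.fixture
def toy_table() -> MarkerTable:
    """Two types over three genes: A:{G1:+1, G2:+1}, B:{G2:+1, G3:-1}."""
    return MarkerTable(
        pd.DataFrame(
            {"A": [1.0, 1.0, 0.0], "B": [0.0, 1.0, -1.0]},
            index=["G1", "G2", "G3"],
        )
    )


@pytest.fixture
def toy_normalized(toy_table) -> MarkerTable:
    return normalize_and_restrict(toy_table, ["G1", "G2", "G3"])


@pytest.fixture
def toy_zbin() -> pd.DataFrame:
    """Binarized centroids: cluster 0 -> (1,0,0), cluster 1 -> (0,1,1)."""
    return pd.DataFrame({0: [1, 0, 0], 1: [0, 1, 1]}, index=["G1", "G2", "G3"])


@pytest.fixture(scope="session")
def planted_two_type():
    """Small planted 2-type dataset with pure-type clusters."""
    table = synth_marker_table(2, markers_per_type=4, n_shared=1,
                               n_negative=2, seed=11)
    matrix, truth = synth_expression(table, [120, 80],
                                     n_background_genes=60, seed=12)
    lognorm = normalize(matrix)
    type_index = {t: i for i, t in enumerate(sorted(set(truth.cell_types)))}
    labels = ClusterLabels.from_mapping(
        {c: type_index[t] for c, t in truth.cell_types.items()}
    )
    return table, lognorm, labels, truth


def make_counts(array, genes=None, cells=None) -> ExpressionMatrix:
    array = np.asarray(array, dtype=float)
    genes = genes or [f"g{i}" for i in range(array.shape[0])]
    cells = cells or [f"c{j}" for j in range(array.shape[1])]
    return ExpressionMatrix(pd.DataFrame(array, index=genes, columns=cells))
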