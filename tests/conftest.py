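import numpy as np
import pandas as pd
import pytest

from rcd_essentiality.types import (
    CellLineTable,
    FitnessMatrix,
    GeneID,
    GeneSetCollection,
)


def make_matrix(values, model_ids=None, symbols=None) -> FitnessMatrix:
    """Build a FitnessMatrix from a 2-D array (rows = cell lines)."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    model_ids = model_ids or [f"ACH-{i:06d}" for i in range(1, n + 1)]
    symbols = symbols or [f"G{j + 1}" for j in range(m)]
    genes = [GeneID(s, 1000 + j) for j, s in enumerate(symbols)]
    frame = pd.DataFrame(values, index=pd.Index(model_ids),
                         columns=[g.label for g in genes])
    return FitnessMatrix(frame, genes)


def random_matrix(rng: np.random.Generator, n_lines: int, n_genes: int,
                  missing_rate: float = 0.0) -> FitnessMatrix:
    """Random scores in [-3, 1] with optional missing cells."""
    values = rng.uniform(-3.0, 1.0, (n_lines, n_genes))
    if missing_rate > 0:
        mask = rng.random((n_lines, n_genes)) < missing_rate
        # keep at least one evaluable score per gene
        for j in range(n_genes):
            if mask[:, j].all():
                mask[rng.integers(n_lines), j] = False
        values = np.where(mask, np.nan, values)
    return make_matrix(values)


@pytest.fixture
def tiny_matrix() -> FitnessMatrix:
    """3 genes x 5 lines: g1 always essential, g2 once, g3 never."""
    values = np.array([
        [-2.0, -2.0, 0.0],
        [-2.0, 0.0, 0.0],
        [-2.0, 0.0, 0.0],
        [-2.0, 0.0, 0.0],
        [-2.0, 0.0, 0.0],
    ])
    return make_matrix(values, symbols=["G1", "G2", "G3"])


@pytest.fixture
def tiny_gene_sets() -> GeneSetCollection:
    return GeneSetCollection({"P": ["G1", "G2", "G3"]})


@pytest.fixture
def annotations6() -> CellLineTable:
    """Six lines over three cancer types (3 + 2 + 1)."""
    return CellLineTable(pd.DataFrame({
        "model_id": [f"ACH-{i:06d}" for i in range(1, 7)],
        "cancer_type": ["X", "X", "X", "Y", "Y", "Z"],
    }))
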