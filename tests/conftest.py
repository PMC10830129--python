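import numpy as np
import pandas as pd
import pytest

from predict_ct import (PredictModel, PreferentialExpression, SimulationConfig,
                        generate_dataset, tissue_preferential_expression)


def make_pe(z_matrix, genes=None, cell_types=None, tissue="toy", ddof=0):
    """PreferentialExpression from a raw matrix (rows standardised here)."""
    z_matrix = np.asarray(z_matrix, dtype=float)
    n_g, n_c = z_matrix.shape
    genes = genes or [f"g{i}" for i in range(n_g)]
    cell_types = cell_types or [f"c{j}" for j in range(n_c)]
    z = pd.DataFrame(z_matrix, index=pd.Index(genes, name="gene"),
                     columns=pd.Index(cell_types, name="cell_type"))
    return PreferentialExpression(tissue=tissue, z=z, ddof=ddof)


def standardize_rows(mat, ddof=0):
    mat = np.asarray(mat, dtype=float)
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=ddof, keepdims=True)
    return (mat - mean) / sd


@pytest.fixture(scope="session")
def sim():
    """One default synthetic dataset with its truth, expression and fit."""
    cfg = SimulationConfig(seed=11)
    data, truth = generate_dataset(cfg)
    pe = tissue_preferential_expression(data)
    results = PredictModel(pe, truth.catalog()).fit(reps=500, seed=7)
    return dict(config=cfg, data=data, truth=truth, pe=pe, results=results)
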