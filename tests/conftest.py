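import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from sigcorr.matrix_io import CountMatrix, SignatureDefinition
from sigcorr.qc import NormalizedMatrix


@pytest.fixture
def tiny_matrix() -> CountMatrix:
    """6 genes (2 mito) x 5 cells with hand-checkable counts."""
    genes = ["Cdkn1a", "Star", "Actb", "Gapdh", "mt-Nd1", "MT-CO1"]
    cells = [f"cell{i}" for i in range(5)]
    counts = np.array([
        # c0  c1  c2  c3  c4
        [40,  0,  0, 10,  5],   # Cdkn1a
        [10,  5,  0, 10,  5],   # Star
        [30, 80,  0, 20, 10],   # Actb
        [15, 10,  0, 10, 20],   # Gapdh
        [ 5,  5, 50,  0,  5],   # mt-Nd1
        [ 0,  0, 50,  0,  5],   # MT-CO1
    ])
    return CountMatrix(genes=genes, cells=cells, counts=sp.csr_matrix(counts))


@pytest.fixture
def tiny_annotation(tiny_matrix) -> pd.DataFrame:
    return pd.DataFrame({
        "cluster": ["Lc", "Lc", "Im", "Lc", "Im"],
        "condition": ["Nt", "O50t", "Nt", "O50t", "O50t"],
        "sample": ["s1"] * 5,
    }, index=pd.Index(tiny_matrix.cells, name="barcode"))


def make_normalized(values: np.ndarray, genes=None, cells=None) -> NormalizedMatrix:
    """Wrap a dense gene x cell array as a NormalizedMatrix for direct tests."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{j}" for j in range(values.shape[1])]
    return NormalizedMatrix(genes=genes, cells=cells, values=sp.csr_matrix(values))


def make_annotation(cells, clusters, conditions) -> pd.DataFrame:
    return pd.DataFrame({
        "cluster": clusters,
        "condition": conditions,
        "sample": ["s1"] * len(cells),
    }, index=pd.Index(cells, name="barcode"))


@pytest.fixture
def senescence_signature() -> SignatureDefinition:
    return SignatureDefinition(
        "Senescence_signature",
        ["Cdkn1a", "Cdkn1b", "Cdkn1c", "Cdkn2a", "Cdkn2b", "Cdkn2c", "Cdkn2d"],
    )
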