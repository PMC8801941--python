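"""Cell/gene quality-control filters and depth normalization.

Filter semantics follow the stated thresholds exactly: detected-gene count
strictly above ``min_features`` and strictly below ``max_features``,
mitochondrial percentage strictly below ``max_percent_mt``, and genes kept
when detected in at least ``min_cells_per_gene`` cells (inclusive).

Order of operations is fixed: percent_mt on the raw matrix -> cell filter ->
gene filter -> normalization.  Normalization is plain depth scaling + log1p
(``ln(1 + scale * count / cell_total)``); it deliberately replaces the
variance-stabilizing batch correction used upstream of this pipeline, and no
batch correction is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigError, DegenerateInputError, EmptyResultError
from .matrix_io import CountMatrix

logger = logging.getLogger(__name__)


@dataclass
class QCThresholds:
    min_features: int = 200        # exclusive lower bound
    max_features: int = 7000       # exclusive upper bound
    max_percent_mt: float = 20.0   # exclusive upper bound
    min_cells_per_gene: int = 3    # inclusive lower bound

    def __post_init__(self):
        if not self.min_features < self.max_features:
            raise ConfigError("min_features must be < max_features")
        if not 0.0 <= self.max_percent_mt <= 100.0:
            raise ConfigError("max_percent_mt must be in [0, 100]")
        if self.min_cells_per_gene < 0:
            raise ConfigError("min_cells_per_gene must be >= 0")


@dataclass
class NormalizedMatrix:
    """Depth-normalized, log-transformed expression with CountMatrix identifiers."""

    genes: list
    cells: list
    values: sp.csr_matrix  # gene x cell, float; zero count maps to exactly 0
    scale: float = 10_000.0

    def __post_init__(self):
        self.genes = list(self.genes)
        self.cells = list(self.cells)
        self.values = sp.csr_matrix(self.values, dtype=np.float64)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def gene_index(self) -> dict:
        return {g: i for i, g in enumerate(self.genes)}

    def gene_vector(self, gene: str) -> np.ndarray:
        """Dense per-cell expression of one gene."""
        try:
            i = self.genes.index(gene)
        except ValueError:
            raise KeyError(gene) from None
        return np.asarray(self.values[i, :].todense()).ravel()


def percent_mt(matrix: CountMatrix) -> np.ndarray:
    """Per-cell percentage of counts in mitochondrial genes.

    Cells with zero total counts get 0.0 and a logged flag (they are removed
    by the feature filter anyway).
    """
    totals = matrix.cell_totals()
    mito = np.asarray(matrix.counts[matrix.mito_mask, :].sum(axis=0)).ravel()
    zero = totals == 0
    if zero.any():
        logger.warning("%d cell(s) with zero total counts; percent_mt set to 0", zero.sum())
    out = np.zeros(matrix.n_cells, dtype=float)
    nz = ~zero
    out[nz] = 100.0 * mito[nz] / totals[nz]
    return out


def filter_cells(matrix: CountMatrix, thresholds: QCThresholds = QCThresholds()) -> CountMatrix:
    """Keep cells passing all three strict bounds; order preserved."""
    nfeat = matrix.features_per_cell()
    pmt = percent_mt(matrix)
    keep = (
        (nfeat > thresholds.min_features)
        & (nfeat < thresholds.max_features)
        & (pmt < thresholds.max_percent_mt)
    )
    if not keep.any():
        raise EmptyResultError("cell filter removed every cell")
    return matrix.subset_cells(np.flatnonzero(keep))


def filter_genes(matrix: CountMatrix, thresholds: QCThresholds = QCThresholds()) -> CountMatrix:
    """Keep genes detected (count > 0) in >= min_cells_per_gene cells."""
    keep = matrix.cells_per_gene() >= thresholds.min_cells_per_gene
    if not keep.any():
        raise EmptyResultError("gene filter removed every gene")
    return matrix.subset_genes(np.flatnonzero(keep))


def run_qc(matrix: CountMatrix, thresholds: QCThresholds = QCThresholds()) -> tuple:
    """Full QC pass: cell filter then gene filter.

    Returns ``(filtered_matrix, report)`` where the report is a one-row
    DataFrame of before/after counts for the QC TSV.
    """
    nfeat = matrix.features_per_cell()
    pmt = percent_mt(matrix)
    n_low = int((nfeat <= thresholds.min_features).sum())
    n_high = int((nfeat >= thresholds.max_features).sum())
    n_mt = int((pmt >= thresholds.max_percent_mt).sum())
    cells_ok = filter_cells(matrix, thresholds)
    out = filter_genes(cells_ok, thresholds)
    report = pd.DataFrame(
        [{
            "cells_before": matrix.n_cells,
            "cells_after": out.n_cells,
            "genes_before": matrix.n_genes,
            "genes_after": out.n_genes,
            "removed_low_features": n_low,
            "removed_high_features": n_high,
            "removed_high_mito": n_mt,
            "removed_genes": matrix.n_genes - out.n_genes,
        }]
    )
    return out, report


def normalize(matrix: CountMatrix, scale: float = 10_000.0) -> NormalizedMatrix:
    """value = ln(1 + scale * count / cell_total); sparse zeros preserved."""
    totals = matrix.cell_totals()
    if (totals == 0).any():
        raise DegenerateInputError(
            f"{int((totals == 0).sum())} cell(s) with zero total counts; filter first"
        )
    csc = matrix.counts.tocsc().astype(np.float64)
    # scale each column (cell) by scale / total, then log1p the stored values
    per_cell = scale / totals
    csc.data *= np.repeat(per_cell, np.diff(csc.indptr))
    np.log1p(csc.data, out=csc.data)
    return NormalizedMatrix(
        genes=matrix.genes, cells=matrix.cells, values=csc.tocsr(), scale=scale
    )
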