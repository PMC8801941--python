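"""Per-cell signature scores as the percentage of all counts in a gene set.

The score of a set S in cell c is ``100 * sum(counts[S, c]) / sum(counts[:, c])``,
computed on raw counts.  It is exactly invariant to per-cell sequencing depth
and sums to 100 over any partition of the gene universe, which makes it the
natural input for Pearson screening across cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .matrix_io import CountMatrix, SignatureDefinition, restrict_signature

logger = logging.getLogger(__name__)


@dataclass
class ScoreVector:
    name: str
    scores: np.ndarray  # per-cell percent, aligned to matrix.cells
    n_genes_used: int
    n_genes_missing: int


def score_signature(matrix: CountMatrix, signature: SignatureDefinition) -> ScoreVector:
    """Percentage-of-counts score of one signature for every cell.

    Raises if no signature gene is measured or any cell has zero total counts.
    """
    totals = matrix.cell_totals()
    if (totals == 0).any():
        raise DegenerateInputError("zero-total cell(s); run QC first")
    present, n_missing = restrict_signature(signature, matrix)
    gidx = matrix.gene_index()
    rows = np.array([gidx[g] for g in present])
    in_set = np.asarray(matrix.counts[rows, :].sum(axis=0)).ravel()
    return ScoreVector(
        name=signature.name,
        scores=100.0 * in_set / totals,
        n_genes_used=len(present),
        n_genes_missing=n_missing,
    )


def score_table(
    matrix: CountMatrix,
    signatures,
    annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One column of scores per signature, aligned on cells.

    When an annotation is given, its ``cluster`` and ``condition`` columns are
    attached first (this table is the direct input to the correlation screen).
    """
    if not signatures:
        raise DegenerateInputError("no signatures given")
    out = pd.DataFrame(index=pd.Index(matrix.cells, name="barcode"))
    if annotation is not None:
        ann = annotation.reindex(matrix.cells)
        if ann["cluster"].isna().any():
            raise DegenerateInputError("annotation missing for some matrix cells")
        out["cluster"] = ann["cluster"].values
        out["condition"] = ann["condition"].values
    for sig in signatures:
        sv = score_signature(matrix, sig)
        out[sv.name] = sv.scores
    return out


def read_score_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="barcode")


def write_score_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=True)
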