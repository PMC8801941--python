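"""Reading and writing the standard single-cell artifacts the pipeline touches.

Count matrices live on disk as a 10x-style MatrixMarket triplet
(``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``), genes as rows and
cells as columns.  Signatures are GMT or two-column TSV.  Cell annotations
are a TSV with header ``barcode<TAB>cluster<TAB>condition[<TAB>sample]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import ConfigError, MatrixFormatError

logger = logging.getLogger(__name__)

#: Case-insensitive gene-symbol prefix that flags a mitochondrial gene
#: (mouse nomenclature, e.g. ``mt-Nd1``).
MITO_PREFIX = "mt-"

ANNOTATION_COLUMNS = ("cluster", "condition", "sample")


def mito_mask_from_names(genes) -> np.ndarray:
    """Boolean mask of genes whose symbol starts with ``mt-`` (any case)."""
    return np.array([g.lower().startswith(MITO_PREFIX) for g in genes], dtype=bool)


@dataclass
class CountMatrix:
    """Sparse gene x cell raw UMI counts plus identifiers and mito flags.

    The single source of truth for all downstream scoring: every percentage
    score, QC statistic and normalized value is derived from it.
    """

    genes: list
    cells: list
    counts: sp.csr_matrix  # gene x cell, nonnegative integers
    mito_mask: np.ndarray = field(default=None)

    def __post_init__(self):
        self.genes = list(self.genes)
        self.cells = list(self.cells)
        if len(set(self.genes)) != len(self.genes):
            raise MatrixFormatError("duplicate gene symbols")
        if len(set(self.cells)) != len(self.cells):
            raise MatrixFormatError("duplicate cell barcodes")
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise MatrixFormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise MatrixFormatError("negative counts")
        if not np.issubdtype(self.counts.dtype, np.integer):
            data = self.counts.data
            if self.counts.nnz and not np.array_equal(data, np.floor(data)):
                raise MatrixFormatError("non-integer counts")
            self.counts = self.counts.astype(np.int64)
        if self.mito_mask is None:
            self.mito_mask = mito_mask_from_names(self.genes)
        self.mito_mask = np.asarray(self.mito_mask, dtype=bool)
        if self.mito_mask.shape != (len(self.genes),):
            raise MatrixFormatError("mito_mask length does not match gene count")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell_totals(self) -> np.ndarray:
        """Total UMI counts per cell."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def features_per_cell(self) -> np.ndarray:
        """Number of detected (count > 0) genes per cell (nFeature)."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def cells_per_gene(self) -> np.ndarray:
        """Number of cells with a nonzero count, per gene."""
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()

    def gene_index(self) -> dict:
        return {g: i for i, g in enumerate(self.genes)}

    def subset_cells(self, idx) -> "CountMatrix":
        idx = np.asarray(idx)
        return CountMatrix(
            genes=self.genes,
            cells=[self.cells[i] for i in idx],
            counts=self.counts[:, idx],
            mito_mask=self.mito_mask,
        )

    def subset_genes(self, idx) -> "CountMatrix":
        idx = np.asarray(idx)
        return CountMatrix(
            genes=[self.genes[i] for i in idx],
            cells=self.cells,
            counts=self.counts[idx, :],
            mito_mask=self.mito_mask[idx],
        )


@dataclass
class SignatureDefinition:
    """A named gene list (signature, pathway, or any gene set)."""

    name: str
    genes: list

    def __post_init__(self):
        if not self.name:
            raise ConfigError("signature name must be non-empty")
        deduped = list(dict.fromkeys(self.genes))
        if len(deduped) != len(self.genes):
            logger.warning(
                "signature %s: %d duplicate gene(s) removed",
                self.name, len(self.genes) - len(deduped),
            )
        self.genes = deduped
        if not self.genes:
            raise ConfigError(f"signature {self.name!r} has an empty gene list")


def read_mtx(path) -> CountMatrix:
    """Read a 10x-style triplet directory into a :class:`CountMatrix`.

    Expects ``matrix.mtx`` (genes as rows), ``features.tsv`` (first column =
    gene symbol) and ``barcodes.tsv``, one identifier per line, in file order.
    """
    path = Path(path)
    for name in ("matrix.mtx", "features.tsv", "barcodes.tsv"):
        if not (path / name).exists():
            raise MatrixFormatError(f"missing {name} in {path}")
    mat = scipy.io.mmread(path / "matrix.mtx")
    if not np.issubdtype(mat.dtype, np.integer):
        if mat.size and not np.array_equal(mat.data, np.floor(mat.data)):
            raise MatrixFormatError("matrix.mtx contains non-integer entries")
        mat = mat.astype(np.int64)
    genes = [
        line.split("\t")[0]
        for line in (path / "features.tsv").read_text().splitlines()
        if line.strip()
    ]
    cells = [
        line.split("\t")[0]
        for line in (path / "barcodes.tsv").read_text().splitlines()
        if line.strip()
    ]
    if mat.shape[0] != len(genes):
        raise MatrixFormatError(
            f"matrix.mtx declares {mat.shape[0]} genes but features.tsv lists {len(genes)}"
        )
    if mat.shape[1] != len(cells):
        raise MatrixFormatError(
            f"matrix.mtx declares {mat.shape[1]} cells but barcodes.tsv lists {len(cells)}"
        )
    return CountMatrix(genes=genes, cells=cells, counts=sp.csr_matrix(mat))


def write_mtx(matrix: CountMatrix, path) -> None:
    """Write the triplet in canonical (row-major, sorted) MatrixMarket order."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    coo = matrix.counts.tocsr().tocoo()  # tocoo() of CSR yields row-major order
    scipy.io.mmwrite(path / "matrix.mtx", coo, field="integer")
    (path / "features.tsv").write_text("".join(f"{g}\n" for g in matrix.genes))
    (path / "barcodes.tsv").write_text("".join(f"{c}\n" for c in matrix.cells))


def read_signatures(path, fmt: str | None = None) -> list:
    """Parse signature definitions from a GMT or two-column TSV file.

    TSV dialect: header ``signature<TAB>gene``, one gene per row.  The format
    is inferred from the extension when ``fmt`` is None.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gmt" if path.suffix.lower() == ".gmt" else "tsv"
    if fmt not in ("gmt", "tsv"):
        raise ConfigError(f"unknown signature format {fmt!r}")
    sigs: list[SignatureDefinition] = []
    if fmt == "gmt":
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise MatrixFormatError(f"GMT line with <3 fields: {line!r}")
            sigs.append(SignatureDefinition(name=parts[0], genes=[p for p in parts[2:] if p]))
    else:
        df = pd.read_csv(path, sep="\t")
        if df.shape[1] < 2:
            raise MatrixFormatError("signature TSV needs two columns: signature, gene")
        name_col, gene_col = df.columns[:2]
        for name, grp in df.groupby(name_col, sort=False):
            sigs.append(SignatureDefinition(name=str(name), genes=[str(g) for g in grp[gene_col]]))
    names = [s.name for s in sigs]
    if len(set(names)) != len(names):
        raise MatrixFormatError("duplicate signature names")
    return sigs


def write_signatures_gmt(signatures, path) -> None:
    with open(path, "w") as fh:
        for s in signatures:
            fh.write("\t".join([s.name, "na"] + list(s.genes)) + "\n")


def restrict_signature(sig: SignatureDefinition, matrix: CountMatrix) -> tuple:
    """Drop signature genes absent from the matrix.

    Returns ``(present_genes, n_missing)``.  Missing genes are logged; a
    signature with no measured genes at all is an error.
    """
    present = [g for g in sig.genes if g in set(matrix.genes)]
    n_missing = len(sig.genes) - len(present)
    if n_missing:
        logger.warning("signature %s: %d gene(s) not in matrix", sig.name, n_missing)
    if not present:
        raise EmptySignatureError(f"no gene of signature {sig.name!r} is in the matrix")
    return present, n_missing


class EmptySignatureError(MatrixFormatError):
    """Every gene of a signature is absent from the matrix."""


def read_annotation(path) -> pd.DataFrame:
    """Read the cell-annotation TSV into a barcode-indexed frame.

    Columns: ``cluster``, ``condition`` and (optional, defaulted) ``sample``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "barcode" not in df.columns:
        raise MatrixFormatError("annotation TSV must have a 'barcode' column")
    for col in ("cluster", "condition"):
        if col not in df.columns:
            raise MatrixFormatError(f"annotation TSV must have a {col!r} column")
    if "sample" not in df.columns:
        df["sample"] = df["condition"]
    if df["barcode"].duplicated().any():
        raise MatrixFormatError("duplicate barcodes in annotation")
    return df.set_index("barcode")[list(ANNOTATION_COLUMNS)]


def write_annotation(annotation: pd.DataFrame, path) -> None:
    out = annotation.copy()
    out.index.name = "barcode"
    out.reset_index().to_csv(path, sep="\t", index=False)


def check_annotation(annotation: pd.DataFrame, matrix: CountMatrix) -> None:
    """Every annotated barcode must be in the matrix and vice versa."""
    ann = set(annotation.index)
    mat = set(matrix.cells)
    missing = mat - ann
    if missing:
        raise MatrixFormatError(f"{len(missing)} matrix barcode(s) lack annotation")
    extra = ann - mat
    if extra:
        raise MatrixFormatError(f"{len(extra)} annotated barcode(s) not in matrix")


def align_annotation(annotation: pd.DataFrame, matrix: CountMatrix) -> pd.DataFrame:
    """Annotation reindexed to the matrix cell order (validated first)."""
    check_annotation(annotation, matrix)
    return annotation.reindex(matrix.cells)
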