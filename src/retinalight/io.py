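"""Sparse count-matrix container and Cell-Ranger-style MTX triplet I/O.

Files on disk follow the 10x convention: ``matrix.mtx`` stores genes x cells
in Matrix Market coordinate integer format with 1-based indices, alongside
``barcodes.tsv`` and ``features.tsv``. In memory the orientation is
cells x genes; the transpose happens at the boundary. Reads are
gzip-transparent (``.gz`` suffixes are detected automatically).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

CONDITIONS = ("dark", "light")

MATRIX_FILE = "matrix.mtx"
BARCODES_FILE = "barcodes.tsv"
FEATURES_FILE = "features.tsv"


class MatrixFormatError(ValueError):
    """Raised for malformed or inconsistent MTX triplets."""


def _as_str_array(values) -> np.ndarray:
    return np.asarray(list(values), dtype=object)


@dataclass
class GeneExpressionMatrix:
    """UMI counts for one sample: cells x genes, sparse, integer.

    Parameters
    ----------
    barcodes, genes
        Ordered, unique cell and gene identifiers.
    counts
        Sparse non-negative integer matrix, shape (n_cells, n_genes).
    condition
        Optional per-cell label, one of ``dark``/``light`` (a scalar is
        broadcast to all cells).
    true_type
        Optional per-cell ground-truth type (synthetic data only).
    """

    barcodes: np.ndarray
    genes: np.ndarray
    counts: sp.csr_matrix
    condition: np.ndarray | None = None
    true_type: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.barcodes = _as_str_array(self.barcodes)
        self.genes = _as_str_array(self.genes)
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()
        if self.counts.shape != (len(self.barcodes), len(self.genes)):
            raise MatrixFormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.barcodes)} barcodes x {len(self.genes)} genes"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise MatrixFormatError("duplicate barcodes")
        if len(set(self.genes)) != len(self.genes):
            raise MatrixFormatError("duplicate gene symbols")
        if self.counts.nnz:
            data = self.counts.data
            if not np.issubdtype(data.dtype, np.integer):
                if not np.allclose(data, np.round(data)):
                    raise MatrixFormatError("counts must be integral")
                self.counts.data = np.round(data).astype(np.int64)
            if self.counts.data.min(initial=0) < 0:
                raise MatrixFormatError("counts must be non-negative")
        if isinstance(self.condition, str):
            self.condition = np.full(len(self.barcodes), self.condition, dtype=object)
        for name in ("condition", "true_type"):
            vec = getattr(self, name)
            if vec is not None:
                vec = _as_str_array(vec)
                if len(vec) != len(self.barcodes):
                    raise MatrixFormatError(f"{name} length mismatch")
                setattr(self, name, vec)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def subset(self, mask) -> "GeneExpressionMatrix":
        """Row-subset (boolean mask or integer indices), order preserved."""
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GeneExpressionMatrix(
            barcodes=self.barcodes[idx],
            genes=self.genes,
            counts=self.counts[idx],
            condition=None if self.condition is None else self.condition[idx],
            true_type=None if self.true_type is None else self.true_type[idx],
        )

    def to_anndata(self):
        """Convert to :class:`anndata.AnnData` (optional dependency)."""
        import anndata

        obs = pd.DataFrame(index=pd.Index(self.barcodes.astype(str), name="barcode"))
        if self.condition is not None:
            obs["condition"] = self.condition.astype(str)
        if self.true_type is not None:
            obs["true_type"] = self.true_type.astype(str)
        var = pd.DataFrame(index=pd.Index(self.genes.astype(str), name="gene"))
        return anndata.AnnData(X=self.counts.astype(np.float32), obs=obs, var=var)


def _open_maybe_gz(path: Path, mode: str = "rt") -> IO:
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _resolve(directory: Path, name: str) -> Path:
    plain = directory / name
    if plain.exists():
        return plain
    gz = directory / (name + ".gz")
    if gz.exists():
        return gz
    raise FileNotFoundError(f"neither {plain} nor {gz} exists")


def _read_lines(path: Path) -> list[str]:
    with _open_maybe_gz(path) as fh:
        return [line.rstrip("\n").rstrip("\r") for line in fh if line.strip()]


def read_mtx_triplet(
    directory: str | Path,
    condition: str | None = None,
) -> GeneExpressionMatrix:
    """Read a ``matrix.mtx`` / ``barcodes.tsv`` / ``features.tsv`` triplet.

    The MTX file stores genes x cells; the returned matrix is cells x genes.
    Dimension mismatches between the header and the identifier files, and
    non-integer entries, are rejected.
    """
    directory = Path(directory)
    mtx_path = _resolve(directory, MATRIX_FILE)
    with _open_maybe_gz(mtx_path, "rb") as fh:
        try:
            mat = scipy.io.mmread(fh)
        except Exception as exc:  # pragma: no cover - scipy message varies
            raise MatrixFormatError(f"malformed Matrix Market file: {exc}") from exc
    mat = sp.coo_matrix(mat)
    if mat.nnz and not np.allclose(mat.data, np.round(mat.data)):
        raise MatrixFormatError("matrix entries must be integers")

    barcodes = _read_lines(_resolve(directory, BARCODES_FILE))
    feature_lines = _read_lines(_resolve(directory, FEATURES_FILE))
    features = [line.split("\t") for line in feature_lines]
    # The symbol column (second when present) is authoritative for matching.
    symbols = [f[1] if len(f) > 1 else f[0] for f in features]

    n_genes, n_cells = mat.shape
    if len(symbols) != n_genes:
        raise MatrixFormatError(
            f"features file lists {len(symbols)} genes but matrix header "
            f"declares {n_genes}"
        )
    if len(barcodes) != n_cells:
        raise MatrixFormatError(
            f"barcodes file lists {len(barcodes)} cells but matrix header "
            f"declares {n_cells}"
        )
    counts = sp.csr_matrix(mat.T)
    counts.data = np.round(counts.data).astype(np.int64)
    counts.eliminate_zeros()
    return GeneExpressionMatrix(
        barcodes=barcodes, genes=symbols, counts=counts, condition=condition
    )


def write_mtx_triplet(matrix: GeneExpressionMatrix, directory: str | Path) -> dict[str, Path]:
    """Write a triplet readable by :func:`read_mtx_triplet`.

    Explicitly stored zeros are dropped; indices are 1-based coordinate
    integer format as written by :func:`scipy.io.mmwrite`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    counts = sp.coo_matrix(matrix.counts.T)  # genes x cells on disk
    counts.eliminate_zeros()
    paths = {
        "matrix": directory / MATRIX_FILE,
        "barcodes": directory / BARCODES_FILE,
        "features": directory / FEATURES_FILE,
    }
    scipy.io.mmwrite(paths["matrix"], counts, field="integer")
    with open(paths["barcodes"], "w") as fh:
        for bc in matrix.barcodes:
            fh.write(f"{bc}\n")
    with open(paths["features"], "w") as fh:
        for gene in matrix.genes:
            fh.write(f"{gene}\t{gene}\tGene Expression\n")
    return paths
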