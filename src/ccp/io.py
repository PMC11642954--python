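"""Expression-matrix containers, readers/writers, and the normalization recipe.

The package works on a cells × genes matrix throughout.  Readers accept the
three formats common in single-cell work — Matrix Market triplets with 10x-style
TSV sidecars, dense CSV/TSV with a gene-name header, and ``.h5ad`` — and always
return the matrix oriented cells × genes (10x stores genes × cells on disk and
is transposed on read).

Normalization follows the usual count-depth recipe: each cell (row) is divided
by its total count and rescaled by the median total count, then log1p is
applied.  Stages are tracked explicitly (``raw`` → ``count_normalized`` →
``log_normalized``) so a matrix cannot be normalized twice by accident.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

STAGES = ("raw", "count_normalized", "log_normalized")

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "write_expression",
    "normalize_counts",
    "log1p_transform",
    "drop_zero_cells",
    "drop_zero_genes",
    "write_matrix_csv",
]


@dataclass
class ExpressionMatrix:
    """A cells × genes non-negative expression matrix with identifiers.

    Parameters
    ----------
    values
        Dense ``(M, I)`` array of non-negative reals; rows are cells.
    cell_ids, gene_ids
        Unique string identifiers for rows and columns.
    stage
        Processing stage, one of ``raw``, ``count_normalized``,
        ``log_normalized``.
    """

    values: np.ndarray
    cell_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D cells x genes array")
        m, i = self.values.shape
        if not self.cell_ids:
            self.cell_ids = [f"cell_{j + 1:04d}" for j in range(m)]
        if not self.gene_ids:
            self.gene_ids = [f"gene_{j + 1:04d}" for j in range(i)]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if len(self.cell_ids) != m:
            raise ValueError(f"{len(self.cell_ids)} cell_ids for {m} rows")
        if len(self.gene_ids) != i:
            raise ValueError(f"{len(self.gene_ids)} gene_ids for {i} columns")
        if len(set(self.cell_ids)) != m:
            raise ValueError("duplicate cell identifiers")
        if len(set(self.gene_ids)) != i:
            raise ValueError("duplicate gene identifiers")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if np.isnan(self.values).any():
            raise ValueError("expression values contain NaN")
        if (self.values < 0).any():
            bad = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative expression value at cell {self.cell_ids[bad[0]]!r}, "
                f"gene {self.gene_ids[bad[1]]!r}"
            )

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, stage: str) -> "ExpressionMatrix":
        """Return a copy with new values and stage (identifiers shared)."""
        return ExpressionMatrix(values, list(self.cell_ids), list(self.gene_ids), stage)


def _read_sidecar_ids(path: Path) -> list[str] | None:
    if not path.exists():
        return None
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return df.iloc[:, 0].tolist()


def _read_mtx(path: Path) -> ExpressionMatrix:
    """Read a 10x-convention Matrix Market directory (or matrix file).

    On disk the matrix is genes × cells; the result is transposed to
    cells × genes.  ``features.tsv``/``genes.tsv`` supplies gene ids (first
    column), ``barcodes.tsv`` the cell ids; missing sidecars fall back to
    synthesized identifiers.
    """
    if path.is_dir():
        mtx = path / "matrix.mtx"
        if not mtx.exists():
            raise FileNotFoundError(f"no matrix.mtx found in {path}")
        base = path
    else:
        mtx = path
        base = path.parent
    try:
        mat = scipy.io.mmread(mtx)
    except Exception as exc:  # scipy raises bare ValueError with line info
        raise ValueError(f"malformed Matrix Market file {mtx}: {exc}") from exc
    dense = np.asarray(
        mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=np.float64
    ).T  # genes x cells on disk -> cells x genes
    gene_ids = _read_sidecar_ids(base / "features.tsv") or _read_sidecar_ids(
        base / "genes.tsv"
    )
    cell_ids = _read_sidecar_ids(base / "barcodes.tsv")
    return ExpressionMatrix(dense, cell_ids or [], gene_ids or [], stage="raw")


def _read_csv(path: Path, sep: str) -> ExpressionMatrix:
    try:
        raw_header = pd.read_csv(path, sep=sep, header=None, nrows=1, dtype=str)
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:
        raise ValueError(f"malformed delimited file {path}: {exc}") from exc
    header = raw_header.iloc[0].tolist()  # pandas de-duplicates df.columns
    if len(set(header)) != len(header):
        raise ValueError(f"duplicate column identifiers in {path}")
    cell_ids: list[str] = []
    if df.shape[1] and df[df.columns[0]].dtype == object:
        cell_ids = df[df.columns[0]].astype(str).tolist()
        df = df.drop(columns=df.columns[0])
    values = df.to_numpy(dtype=np.float64)
    return ExpressionMatrix(values, cell_ids, [str(c) for c in df.columns], stage="raw")


def _read_h5ad(path: Path) -> ExpressionMatrix:
    import anndata

    adata = anndata.read_h5ad(path)
    x = adata.X
    dense = np.asarray(x.todense() if scipy.sparse.issparse(x) else x, dtype=np.float64)
    return ExpressionMatrix(
        dense, adata.obs_names.tolist(), adata.var_names.tolist(), stage="raw"
    )


def read_expression(path: str | Path, format: str = "auto") -> ExpressionMatrix:
    """Read an expression matrix, returning it oriented cells × genes.

    Parameters
    ----------
    path
        File (``.mtx``, ``.csv``, ``.tsv``, ``.h5ad``) or a 10x-style
        directory containing ``matrix.mtx`` plus sidecars.
    format
        One of ``mtx``, ``csv``, ``tsv``, ``h5ad`` or ``auto`` (from suffix).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        if path.is_dir() or path.suffix == ".mtx":
            format = "mtx"
        elif path.suffix == ".h5ad":
            format = "h5ad"
        elif path.suffix == ".tsv":
            format = "tsv"
        elif path.suffix == ".csv":
            format = "csv"
        else:
            raise ValueError(f"cannot infer format of {path}; pass format= explicitly")
    if format == "mtx":
        return _read_mtx(path)
    if format == "csv":
        return _read_csv(path, ",")
    if format == "tsv":
        return _read_csv(path, "\t")
    if format == "h5ad":
        return _read_h5ad(path)
    raise ValueError(f"unknown format {format!r}")


def write_expression(x: ExpressionMatrix, path: str | Path, format: str = "auto") -> Path:
    """Write an expression matrix as CSV (cells in rows, gene header) or as a
    Matrix Market directory in the 10x genes × cells convention."""
    path = Path(path)
    if format == "auto":
        format = "mtx" if (path.suffix == "" or path.suffix == ".mtx") else path.suffix[1:]
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = pd.DataFrame(x.values, index=x.cell_ids, columns=x.gene_ids)
        df.index.name = "cell_id"
        df.to_csv(path, sep=sep)
        return path
    if format == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(path / "matrix.mtx", scipy.sparse.coo_matrix(x.values.T))
        pd.Series(x.gene_ids).to_csv(path / "genes.tsv", sep="\t", index=False, header=False)
        pd.Series(x.cell_ids).to_csv(path / "barcodes.tsv", sep="\t", index=False, header=False)
        return path
    raise ValueError(f"unknown format {format!r}")


def normalize_counts(x: ExpressionMatrix) -> ExpressionMatrix:
    """Depth-normalize: divide each cell by its row sum, rescale by the median
    row sum.

    The median is the lower median for even cell counts, so the result is
    deterministic across platforms.  All-zero cells are an error (dropping
    them silently would desynchronize labels); remove them first with
    :func:`drop_zero_cells`.
    """
    if x.stage != "raw":
        raise ValueError(f"normalize_counts expects stage 'raw', got {x.stage!r}")
    row_sums = x.values.sum(axis=1)
    zero = np.flatnonzero(row_sums == 0)
    if zero.size:
        ids = [x.cell_ids[i] for i in zero[:20]]
        raise ValueError(
            f"{zero.size} all-zero cell(s) cannot be depth-normalized: {ids}; "
            "drop them first with drop_zero_cells()"
        )
    median = float(np.sort(row_sums)[(len(row_sums) - 1) // 2])  # lower median
    values = x.values * (median / row_sums)[:, None]
    return x.with_values(values, "count_normalized")


def log1p_transform(x: ExpressionMatrix) -> ExpressionMatrix:
    """Apply y = ln(1 + x) entrywise; zeros stay zero."""
    if x.stage != "count_normalized":
        raise ValueError(
            f"log1p_transform expects stage 'count_normalized', got {x.stage!r}"
        )
    return x.with_values(np.log1p(x.values), "log_normalized")


def drop_zero_cells(x: ExpressionMatrix) -> ExpressionMatrix:
    """Remove cells whose total count is zero (explicit, never implicit)."""
    keep = np.flatnonzero(x.values.sum(axis=1) > 0)
    if keep.size == x.n_cells:
        return x
    warnings.warn(f"dropping {x.n_cells - keep.size} all-zero cell(s)")
    return ExpressionMatrix(
        x.values[keep], [x.cell_ids[i] for i in keep], list(x.gene_ids), x.stage
    )


def drop_zero_genes(x: ExpressionMatrix) -> ExpressionMatrix:
    """Remove genes with zero total count.  Optional; off by default in the
    pipeline since retained zero genes simply fall into the low-variance set."""
    keep = np.flatnonzero(x.values.sum(axis=0) > 0)
    if keep.size == x.n_genes:
        return x
    return ExpressionMatrix(
        x.values[:, keep], list(x.cell_ids), [x.gene_ids[i] for i in keep], x.stage
    )


def write_matrix_csv(
    values: np.ndarray, cell_ids: list[str], columns: list[str], path: str | Path
) -> Path:
    """Write any per-cell matrix (super-genes, 2-D embeddings) as CSV with
    cell ids in the first column."""
    path = Path(path)
    df = pd.DataFrame(np.asarray(values), index=list(cell_ids), columns=list(columns))
    df.index.name = "cell_id"
    df.to_csv(path)
    return path
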