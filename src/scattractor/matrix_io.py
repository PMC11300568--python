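"""Reading, validation, normalization and filtering of expression matrices.

The in-memory carrier is :class:`ExpressionMatrix`: a dense gene x cell
array of nonnegative values with ordered, unique gene and cell identifiers
and a ``layer`` flag distinguishing raw counts from log-normalized values.
Supported on-disk forms are the 10x Genomics MatrixMarket triplet
(``matrix.mtx`` + ``features.tsv``/``genes.tsv`` + ``barcodes.tsv``,
optionally gzipped) and dense delimited tables. Gene lists are plain text,
one symbol per line, ``#`` comments ignored.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


__all__ = [
    "ExpressionMatrix",
    "GeneList",
    "MatrixFormatError",
    "MatrixValidationError",
    "read_10x_triplet",
    "write_10x_triplet",
    "read_dense_table",
    "write_dense_table",
    "read_gene_list",
    "write_gene_list",
    "normalize_log",
    "filter_genes",
]


class MatrixFormatError(ValueError):
    """A file's structure contradicts its declared format."""


class MatrixValidationError(ValueError):
    """In-memory values violate an ExpressionMatrix invariant."""


def _dedup_ids(ids: list[str], what: str) -> list[str]:
    """Resolve duplicate identifiers by suffixing ``.1``, ``.2``... in file order."""
    seen: dict[str, int] = {}
    out = []
    n_dup = 0
    for x in ids:
        if x in seen:
            seen[x] += 1
            n_dup += 1
            out.append(f"{x}.{seen[x]}")
        else:
            seen[x] = 0
            out.append(x)
    if n_dup:
        warnings.warn(
            f"{n_dup} duplicate {what} identifier(s) resolved by .1/.2 suffixing",
            stacklevel=3,
        )
    return out


@dataclass
class ExpressionMatrix:
    """Dense gene x cell expression matrix.

    Parameters
    ----------
    gene_ids, cell_ids
        Ordered unique identifiers; rows of ``values`` follow ``gene_ids``,
        columns follow ``cell_ids``.
    values
        Nonnegative finite floats, shape ``(len(gene_ids), len(cell_ids))``.
    layer
        ``"counts"`` (integral values) or ``"lognorm"``.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray
    layer: str = "counts"

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.layer not in ("counts", "lognorm"):
            raise MatrixValidationError(f"unknown layer {self.layer!r}")
        if self.values.ndim != 2 or self.values.shape != (
            len(self.gene_ids),
            len(self.cell_ids),
        ):
            raise MatrixValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise MatrixValidationError("duplicate gene identifiers")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise MatrixValidationError("duplicate cell identifiers")
        if not np.all(np.isfinite(self.values)):
            raise MatrixValidationError("non-finite expression values")
        if np.any(self.values < 0):
            raise MatrixValidationError("negative expression values")
        if self.layer == "counts" and not np.all(
            self.values == np.round(self.values)
        ):
            raise MatrixValidationError("layer='counts' requires integral values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self, gene: str) -> int:
        """Position of ``gene`` (exact, case-sensitive match)."""
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def expression(self, gene: str) -> np.ndarray:
        """The expression vector of one gene across cells."""
        return self.values[self.gene_index(gene)]


@dataclass(frozen=True)
class GeneList:
    """Named, ordered, duplicate-free list of gene symbols.

    May be empty in memory (e.g. an empty intersection); reading an empty
    file is an error.
    """

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene list {self.name!r} contains duplicates")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


def _open_maybe_gz(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _find_file(directory: Path, stems: list[str]) -> Path:
    for stem in stems:
        for name in (stem, stem + ".gz"):
            p = directory / name
            if p.exists():
                return p
    raise FileNotFoundError(
        f"none of {stems} (or .gz variants) found in {directory}"
    )


def read_10x_triplet(directory_path: str | Path) -> ExpressionMatrix:
    """Read a 10x-style triplet directory into a counts matrix.

    Expects a MatrixMarket coordinate file (genes as rows) plus a feature
    table (``features.tsv`` or ``genes.tsv``: id column, optional symbol
    column) and a barcode table. When a symbol column is present, symbols
    become the gene identifiers (duplicates suffixed ``.1``, ``.2``...).
    Implicit zeros are materialized; gene order follows the feature file.
    """
    directory_path = Path(directory_path)
    if not directory_path.is_dir():
        raise FileNotFoundError(f"not a directory: {directory_path}")
    mtx_path = _find_file(directory_path, ["matrix.mtx"])
    feat_path = _find_file(directory_path, ["features.tsv", "genes.tsv"])
    bc_path = _find_file(directory_path, ["barcodes.tsv"])

    with _open_maybe_gz(mtx_path) as fh:
        mat = scipy.io.mmread(fh)
    mat = scipy.sparse.coo_matrix(mat)

    feats = pd.read_csv(feat_path, sep="\t", header=None, dtype=str)
    barcodes = pd.read_csv(bc_path, sep="\t", header=None, dtype=str)[0].tolist()

    if mat.shape[0] != len(feats):
        raise MatrixFormatError(
            f"matrix declares {mat.shape[0]} rows but feature table "
            f"{feat_path.name} has {len(feats)} entries"
        )
    if mat.shape[1] != len(barcodes):
        raise MatrixFormatError(
            f"matrix declares {mat.shape[1]} columns but barcode table "
            f"{bc_path.name} has {len(barcodes)} entries"
        )

    # symbol column preferred: downstream gene lists use symbols
    gene_col = 1 if feats.shape[1] > 1 else 0
    gene_ids = _dedup_ids(feats[gene_col].tolist(), "feature")
    cell_ids = _dedup_ids(barcodes, "barcode")

    return ExpressionMatrix(gene_ids, cell_ids, mat.toarray(), layer="counts")


def write_10x_triplet(matrix: ExpressionMatrix, directory_path: str | Path) -> None:
    """Write ``matrix`` as an uncompressed MatrixMarket triplet directory."""
    directory_path = Path(directory_path)
    directory_path.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(matrix.values)
    if matrix.layer == "counts":
        sparse = sparse.astype(np.int64)
    scipy.io.mmwrite(str(directory_path / "matrix.mtx"), sparse)
    with open(directory_path / "features.tsv", "w") as fh:
        for g in matrix.gene_ids:
            fh.write(f"{g}\t{g}\n")
    with open(directory_path / "barcodes.tsv", "w") as fh:
        fh.write("\n".join(matrix.cell_ids) + "\n")


def _sniff_sep(path: Path) -> str:
    name = path.name[:-3] if path.suffix == ".gz" else path.name
    return "," if name.endswith(".csv") else "\t"


def read_dense_table(
    path: str | Path, genes_in_rows: bool = True
) -> ExpressionMatrix:
    """Read a dense delimited gene x cell (or cell x gene) table.

    The delimiter is sniffed from the extension (``.csv`` -> comma, else
    tab). Layer is inferred: all-integral values -> ``counts``, otherwise
    ``lognorm``. Negative entries are a validation error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    if not genes_in_rows:
        df = df.T
    values = df.to_numpy(dtype=np.float64)
    if np.any(values < 0):
        raise MatrixValidationError(f"negative expression values in {path}")
    layer = "counts" if np.all(values == np.round(values)) else "lognorm"
    gene_ids = _dedup_ids([str(x) for x in df.index], "gene")
    cell_ids = _dedup_ids([str(x) for x in df.columns], "cell")
    return ExpressionMatrix(gene_ids, cell_ids, values, layer=layer)


def write_dense_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(matrix.values, index=matrix.gene_ids, columns=matrix.cell_ids)
    if matrix.layer == "counts":
        df = df.astype(np.int64)
    df.to_csv(path, sep=_sniff_sep(path))


def read_gene_list(path: str | Path, name: str | None = None) -> GeneList:
    """Read a plain-text gene list (one symbol per line, ``#`` comments)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    genes: list[str] = []
    with _open_maybe_gz(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if line in genes:
                warnings.warn(f"duplicate gene {line!r} in {path} ignored")
                continue
            genes.append(line)
    if not genes:
        raise MatrixFormatError(f"gene list file {path} contains no genes")
    return GeneList(name=name or path.stem, genes=tuple(genes))


def write_gene_list(gene_list: GeneList, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(gene_list.genes) + "\n")


def normalize_log(matrix: ExpressionMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Log-normalize counts: per cell, divide by the cell total, multiply by
    ``scale``, then ``log(1+x)``.

    All-zero cells are dropped with a warning (their total is undefined).
    """
    if matrix.layer != "counts":
        raise MatrixValidationError("matrix is already log-normalized")
    if scale <= 0:
        raise ValueError("scale must be positive")
    totals = matrix.values.sum(axis=0)
    keep = totals > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} all-zero cell(s) during normalization")
    values = matrix.values[:, keep]
    cell_ids = [c for c, k in zip(matrix.cell_ids, keep) if k]
    normed = np.log1p(values / totals[keep] * scale)
    return ExpressionMatrix(matrix.gene_ids, cell_ids, normed, layer="lognorm")


def filter_genes(
    matrix: ExpressionMatrix, min_cell_fraction: float = 0.02
) -> ExpressionMatrix:
    """Keep genes expressed (>0) in at least ``min_cell_fraction`` of cells.

    Gene order is preserved; the operation is idempotent at a fixed
    threshold. An empty result is an error.
    """
    if not 0 <= min_cell_fraction <= 1:
        raise ValueError("min_cell_fraction must be in [0, 1]")
    frac = (matrix.values > 0).mean(axis=1)
    keep = frac >= min_cell_fraction
    if not keep.any():
        raise MatrixValidationError(
            "no gene passes the expression filter; lower min_cell_fraction"
        )
    gene_ids = [g for g, k in zip(matrix.gene_ids, keep) if k]
    return ExpressionMatrix(gene_ids, matrix.cell_ids, matrix.values[keep], matrix.layer)
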