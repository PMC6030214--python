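"""Readers and writers for expression matrices, label files, TF lists, and core tables.

Expression matrices arrive as dense TSV/CSV (header row = gene ids, first
column = cell ids) or MatrixMarket MTX with ``barcodes.tsv`` / ``genes.tsv``
sidecars. Orientation is never guessed: the caller declares whether the file
is cells × genes or genes × cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from ._exceptions import DataValidationError
from .config import UNIT_REGIMES

#: label that marks cells excluded from analysis regardless of group size
UNDEFINED_LABEL = "undefined"
#: smallest subpopulation for which a core search is attempted
MIN_CELLS_PER_SUBPOP = 3

_CORE_COLUMNS = ["subpopulation", "rank", "tfs", "mmi", "tc", "summed_mean_expression"]


@dataclass
class ExpressionMatrix:
    """Dense cells × genes expression matrix with a declared unit regime."""

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    unit_regime: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.unit_regime not in UNIT_REGIMES:
            raise DataValidationError(
                f"unknown unit_regime {self.unit_regime!r}; expected one of {UNIT_REGIMES}"
            )
        if self.values.ndim != 2:
            raise DataValidationError("expression values must be a 2-D matrix")
        n_cells, n_genes = self.values.shape
        if n_cells != len(self.cell_ids) or n_genes != len(self.gene_ids):
            raise DataValidationError(
                f"dimension mismatch: values {self.values.shape} vs "
                f"{len(self.cell_ids)} cells / {len(self.gene_ids)} genes"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise DataValidationError("duplicate cell ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataValidationError("duplicate gene ids")
        if not np.isfinite(self.values).all():
            raise DataValidationError("expression values contain NaN/inf")
        if (self.values < 0).any():
            raise DataValidationError("expression values must be non-negative")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._cell_index = {c: i for i, c in enumerate(self.cell_ids)}

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_column(self, gene: str) -> np.ndarray:
        return self.values[:, self._gene_index[gene]]

    def cell_rows(self, cells: list[str]) -> np.ndarray:
        idx = [self._cell_index[c] for c in cells]
        return self.values[idx, :]

    def submatrix(self, cells: list[str], genes: list[str]) -> np.ndarray:
        rows = [self._cell_index[c] for c in cells]
        cols = [self._gene_index[g] for g in genes]
        return self.values[np.ix_(rows, cols)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)

    def to_anndata(self):
        """Export as an AnnData (cells = obs, genes = var) for scanpy interop."""
        import anndata

        ad = anndata.AnnData(X=self.values.copy())
        ad.obs_names = self.cell_ids
        ad.var_names = self.gene_ids
        ad.uns["unit_regime"] = self.unit_regime
        return ad

    @classmethod
    def from_anndata(cls, adata, unit_regime: str) -> "ExpressionMatrix":
        X = adata.X
        if scipy.sparse.issparse(X):
            X = X.toarray()
        return cls(
            values=np.asarray(X, dtype=np.float64),
            cell_ids=list(map(str, adata.obs_names)),
            gene_ids=list(map(str, adata.var_names)),
            unit_regime=unit_regime,
        )


@dataclass
class SubpopulationPartition:
    """Assignment of each cell to exactly one subpopulation label.

    Labels covering fewer than three cells, or the literal label
    ``"undefined"``, are flagged ineligible and skipped by all per-subpopulation
    analyses.
    """

    assignment: dict[str, str]
    _cells_by_label: dict[str, list[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.assignment = {str(c): str(l) for c, l in self.assignment.items()}
        self._cells_by_label = {}
        for cell, label in self.assignment.items():
            self._cells_by_label.setdefault(label, []).append(cell)

    @property
    def labels(self) -> list[str]:
        return sorted(self._cells_by_label)

    def cells(self, label: str) -> list[str]:
        return list(self._cells_by_label[label])

    def complement_cells(self, label: str) -> list[str]:
        return [c for c, l in self.assignment.items() if l != label]

    def is_eligible(self, label: str) -> bool:
        return (
            label != UNDEFINED_LABEL
            and len(self._cells_by_label.get(label, ())) >= MIN_CELLS_PER_SUBPOP
        )

    @property
    def eligible_labels(self) -> list[str]:
        return [l for l in self.labels if self.is_eligible(l)]


def read_expression(
    matrix_path: str | Path,
    format: str,
    unit_regime: str,
    orientation: str = "cells_by_genes",
    cells_path: str | Path | None = None,
    genes_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix from TSV, CSV, or MatrixMarket MTX.

    For MTX, ``cells_path``/``genes_path`` default to ``barcodes.tsv`` /
    ``genes.tsv`` next to the matrix file; rows of the MTX follow
    ``orientation`` just like dense files.
    """
    matrix_path = Path(matrix_path)
    if not matrix_path.exists():
        raise FileNotFoundError(matrix_path)
    if orientation not in ("cells_by_genes", "genes_by_cells"):
        raise DataValidationError(f"unknown orientation {orientation!r}")

    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        # pandas mangles duplicate header names (gA, gA.1): check the raw header
        with open(matrix_path, "r", encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        if len(set(header)) != len(header):
            raise DataValidationError(f"duplicate column ids in {matrix_path}")
        df = pd.read_csv(matrix_path, sep=sep, index_col=0)
        if df.index.has_duplicates:
            raise DataValidationError(f"duplicate row ids in {matrix_path}")
        values = df.to_numpy(dtype=np.float64)
        row_ids = list(map(str, df.index))
        col_ids = list(map(str, df.columns))
    elif format == "mtx":
        cells_path = Path(cells_path) if cells_path else matrix_path.parent / "barcodes.tsv"
        genes_path = Path(genes_path) if genes_path else matrix_path.parent / "genes.tsv"
        for p in (cells_path, genes_path):
            if not p.exists():
                raise FileNotFoundError(p)
        values = np.asarray(scipy.io.mmread(matrix_path).todense(), dtype=np.float64)
        cells = _read_id_list(cells_path)
        genes = _read_id_list(genes_path)
        if orientation == "cells_by_genes":
            row_ids, col_ids = cells, genes
        else:
            row_ids, col_ids = genes, cells
    else:
        raise DataValidationError(f"unknown format {format!r}; expected tsv, csv, or mtx")

    if orientation == "genes_by_cells":
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    return ExpressionMatrix(
        values=values, cell_ids=row_ids, gene_ids=col_ids, unit_regime=unit_regime
    )


def _read_id_list(path: Path) -> list[str]:
    with open(path, "r", encoding="utf-8") as fh:
        return [line.split("\t")[0].strip() for line in fh if line.strip()]


def read_labels(path: str | Path) -> SubpopulationPartition:
    """Read a two-column (cell_id <tab> label) file; empty file → empty partition."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    assignment: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DataValidationError(f"{path}:{lineno}: expected 2 tab-separated fields")
            cell, label = parts[0].strip(), parts[1].strip()
            if cell in assignment and assignment[cell] != label:
                raise DataValidationError(
                    f"{path}:{lineno}: cell {cell!r} listed with conflicting labels"
                )
            assignment[cell] = label
    return SubpopulationPartition(assignment=assignment)


def read_tf_list(path: str | Path) -> list[str]:
    """Read a TF list, one gene symbol per line (e.g. an AnimalTFDB export)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    seen: dict[str, None] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            symbol = line.strip()
            if symbol:
                seen.setdefault(symbol, None)
    return list(seen)


def write_cores(cores, path: str | Path) -> None:
    """Write cores as a tidy TSV (one row per core; TFs semicolon-joined).

    MMI/TC/summed mean expression are printed with enough digits for a
    lossless (12 significant digit) round-trip through :func:`read_cores`.
    """
    rows = []
    for core in cores:
        rows.append(
            {
                "subpopulation": core.subpopulation,
                "rank": core.rank,
                "tfs": ";".join(core.tfs),
                "mmi": f"{core.mmi:.12g}",
                "tc": f"{core.tc:.12g}",
                "summed_mean_expression": f"{core.summed_mean_expression:.12g}",
            }
        )
    pd.DataFrame(rows, columns=_CORE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_cores(path: str | Path):
    """Read a core table written by :func:`write_cores`."""
    from .search import SynergyCore

    df = pd.read_csv(path, sep="\t", dtype={"subpopulation": str})
    cores = []
    for row in df.itertuples(index=False):
        cores.append(
            SynergyCore(
                subpopulation=str(row.subpopulation),
                tfs=tuple(str(row.tfs).split(";")),
                mmi=float(row.mmi),
                tc=float(row.tc),
                summed_mean_expression=float(row.summed_mean_expression),
                rank=int(row.rank),
            )
        )
    return cores
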