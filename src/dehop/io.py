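"""Core data containers and file I/O.

The package works on three tables:

* an expression matrix in TPM (genes as rows, wells/cells as columns),
  read either from a dense TSV or from a MatrixMarket triplet
  (``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv``);
* a well metadata table describing the dual-index plate layout
  (pool, i7 row index, i5 column index, occupancy status, cell type);
* a marker table assigning signature genes to cell types.

Values are accepted as already-normalised TPM; the package never
recomputes TPM from counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("dehop")

WELL_STATUSES = ("cell", "empty", "qc_fail")

WELL_COLUMNS = ("cell_id", "pool_id", "i7_index", "i5_index", "status")


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


@dataclass
class LogTransform:
    """The display/analysis convention log2(TPM + pseudocount)."""

    pseudocount: float = 1.0
    base: float = 2.0

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return np.log(np.asarray(x, dtype=float) + self.pseudocount) / np.log(self.base)


@dataclass
class ExpressionMatrix:
    """A genes x cells matrix of non-negative TPM values.

    Parameters
    ----------
    genes, cells
        Ordered, duplicate-free identifier axes.
    values
        Dense float array of shape ``(len(genes), len(cells))``; all
        entries finite and >= 0.
    corrected
        Guard flag set by the correction step so a matrix is not
        silently corrected twice.
    """

    genes: pd.Index
    cells: pd.Index
    values: np.ndarray
    corrected: bool = False

    def __post_init__(self) -> None:
        self.genes = pd.Index(self.genes, name="gene")
        self.cells = pd.Index(self.cells, name="cell")
        self.values = np.asarray(self.values, dtype=float)
        if len(self.genes) == 0 or len(self.cells) == 0:
            raise ValidationError("expression matrix must have at least one gene and one cell")
        for name, idx in (("gene", self.genes), ("cell", self.cells)):
            if idx.has_duplicates:
                dups = idx[idx.duplicated()].unique().tolist()
                raise ValidationError(f"duplicate {name} identifiers: {dups[:10]}")
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValidationError(
                f"value shape {self.values.shape} does not match "
                f"({len(self.genes)} genes, {len(self.cells)} cells)"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(f"non-finite value at gene row {bad[0]}, cell column {bad[1]}")
        if np.any(self.values < 0):
            bad = np.argwhere(self.values < 0)[0]
            raise ValidationError(f"negative value at gene row {bad[0]}, cell column {bad[1]}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.cells)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, corrected: bool = False) -> "ExpressionMatrix":
        return cls(frame.index, frame.columns, frame.to_numpy(dtype=float), corrected=corrected)

    def subset_cells(self, cell_ids) -> "ExpressionMatrix":
        pos = self.cells.get_indexer(pd.Index(cell_ids))
        if np.any(pos < 0):
            missing = [c for c, p in zip(cell_ids, pos) if p < 0]
            raise ValidationError(f"unknown cell identifiers: {missing[:10]}")
        # ascontiguousarray: column fancy-indexing yields an F-layout view
        # whose row reductions would sum in a different order than the
        # parent matrix (1-ulp drift breaks exact-equality contracts)
        return ExpressionMatrix(
            self.genes,
            pd.Index(cell_ids),
            np.ascontiguousarray(self.values[:, pos]),
            corrected=self.corrected,
        )


@dataclass
class WellTable:
    """Per-well metadata for a pooled dual-indexed plate library.

    One row per well: ``cell_id`` (matching an expression-matrix
    column), ``pool_id`` (pooled sequencing library), ``i7_index``
    (plate row index), ``i5_index`` (plate column index), ``status``
    in {cell, empty, qc_fail}, and ``cell_type`` (required when the
    well holds a cell, absent otherwise).  Empty wells may still carry
    non-zero expression -- that is the index-hopping signal.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        missing = [c for c in WELL_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"well table missing required columns: {missing}")
        if "cell_type" not in df.columns:
            df["cell_type"] = pd.NA
        df["cell_type"] = df["cell_type"].replace("", pd.NA)
        df["cell_type"] = df["cell_type"].where(df["cell_type"].notna(), pd.NA)
        bad_status = sorted(set(df["status"]) - set(WELL_STATUSES))
        if bad_status:
            raise ValidationError(
                f"unknown status values {bad_status}; allowed: {list(WELL_STATUSES)}"
            )
        if df["cell_id"].duplicated().any():
            dups = df.loc[df["cell_id"].duplicated(), "cell_id"].tolist()
            raise ValidationError(f"duplicate cell_id values: {dups[:10]}")
        trip = df[["pool_id", "i7_index", "i5_index"]].astype(str)
        dup_mask = trip.duplicated()
        if dup_mask.any():
            dups = trip[dup_mask].apply(tuple, axis=1).tolist()
            raise ValidationError(f"duplicate (pool, i7, i5) index triples: {dups[:10]}")
        is_cell = df["status"] == "cell"
        if df.loc[is_cell, "cell_type"].isna().any():
            bad = df.loc[is_cell & df["cell_type"].isna(), "cell_id"].tolist()
            raise ValidationError(f"status=cell rows lacking cell_type: {bad[:10]}")
        if df.loc[~is_cell, "cell_type"].notna().any():
            bad = df.loc[~is_cell & df["cell_type"].notna(), "cell_id"].tolist()
            raise ValidationError(f"non-cell wells must not carry a cell_type: {bad[:10]}")
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def cell_ids(self) -> pd.Index:
        return pd.Index(self.frame["cell_id"])

    @property
    def pools(self) -> list:
        return list(pd.unique(self.frame["pool_id"]))

    @property
    def cell_types(self) -> list:
        return list(pd.unique(self.frame.loc[self.frame["status"] == "cell", "cell_type"]))

    def restrict_pool(self, pool_id) -> "WellTable":
        sub = self.frame[self.frame["pool_id"] == pool_id]
        if sub.empty:
            raise ValidationError(f"unknown pool_id {pool_id!r}")
        return WellTable(sub)

    def ids_with_status(self, status: str, pool_id=None) -> pd.Index:
        df = self.frame
        mask = df["status"] == status
        if pool_id is not None:
            mask &= df["pool_id"] == pool_id
        return pd.Index(df.loc[mask, "cell_id"])

    def ids_of_type(self, cell_type, pool_id=None) -> pd.Index:
        df = self.frame
        mask = (df["status"] == "cell") & (df["cell_type"] == cell_type)
        if pool_id is not None:
            mask &= df["pool_id"] == pool_id
        return pd.Index(df.loc[mask, "cell_id"])

    def subset(self, cell_ids) -> "WellTable":
        df = self.frame.set_index("cell_id", drop=False)
        missing = [c for c in cell_ids if c not in df.index]
        if missing:
            raise ValidationError(f"unknown cell identifiers in well table: {missing[:10]}")
        return WellTable(df.loc[list(cell_ids)].reset_index(drop=True))


@dataclass
class MarkerTable:
    """Gene -> cell-type assignments used to define self vs non-self genes."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        for col in ("gene", "cell_type"):
            if col not in df.columns:
                raise ValidationError(f"marker table missing required column {col!r}")
        if "score" not in df.columns:
            df["score"] = np.nan
        if df.duplicated(subset=["gene", "cell_type"]).any():
            dups = df.loc[df.duplicated(subset=["gene", "cell_type"]), "gene"].tolist()
            raise ValidationError(f"duplicate (gene, cell_type) marker pairs: {dups[:10]}")
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def cell_types(self) -> list:
        return list(pd.unique(self.frame["cell_type"]))

    def genes_for(self, cell_type) -> pd.Index:
        return pd.Index(self.frame.loc[self.frame["cell_type"] == cell_type, "gene"])

    def non_self_genes(self, reference_type) -> pd.Index:
        """Marker genes of every type other than ``reference_type``.

        Genes also listed as markers of the reference type itself are
        excluded (they are not non-self).
        """
        self_genes = set(self.genes_for(reference_type))
        mask = self.frame["cell_type"] != reference_type
        genes = self.frame.loc[mask, "gene"]
        return pd.Index(pd.unique(genes[~genes.isin(self_genes)]))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _detect_format(path: Path) -> str:
    if path.is_dir() or path.suffix == ".mtx":
        return "mtx"
    return "tsv"


def read_matrix(path, fmt: str | None = None) -> ExpressionMatrix:
    """Read an expression matrix.

    ``fmt='tsv'``: dense tab-separated file, first column gene ids,
    header row of cell ids.  ``fmt='mtx'``: a MatrixMarket file (or a
    directory containing ``matrix.mtx``) with sidecar ``genes.tsv``
    and ``barcodes.tsv`` name files, genes x cells.
    """
    path = Path(path)
    fmt = fmt or _detect_format(path)
    if fmt == "tsv":
        frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        try:
            values = frame.to_numpy(dtype=float)
        except ValueError as exc:
            raise ValidationError(f"non-numeric entry in {path}: {exc}") from exc
        return ExpressionMatrix(frame.index.astype(str), frame.columns.astype(str), values)
    if fmt == "mtx":
        mtx_path = path / "matrix.mtx" if path.is_dir() else path
        base = mtx_path.parent
        genes = pd.read_csv(base / "genes.tsv", sep="\t", header=None)[0].astype(str)
        cells = pd.read_csv(base / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
        mat = scipy.io.mmread(mtx_path)
        values = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
        return ExpressionMatrix(genes, cells, values)
    raise ValidationError(f"unknown matrix format {fmt!r}")


def write_matrix(matrix: ExpressionMatrix, path, fmt: str | None = None) -> None:
    """Write a matrix in the same layouts :func:`read_matrix` accepts.

    TSV output uses repr-precision floats so a read/write round trip
    is lossless.
    """
    path = Path(path)
    fmt = fmt or _detect_format(path)
    if fmt == "tsv":
        frame = matrix.to_frame()
        frame.index.name = "gene"
        frame.to_csv(path, sep="\t", float_format=None)
    elif fmt == "mtx":
        if path.suffix == ".mtx":
            base, mtx_path = path.parent, path
        else:
            path.mkdir(parents=True, exist_ok=True)
            base, mtx_path = path, path / "matrix.mtx"
        scipy.io.mmwrite(str(mtx_path), scipy.sparse.coo_matrix(matrix.values))
        pd.Series(matrix.genes).to_csv(base / "genes.tsv", sep="\t", header=False, index=False)
        pd.Series(matrix.cells).to_csv(base / "barcodes.tsv", sep="\t", header=False, index=False)
    else:
        raise ValidationError(f"unknown matrix format {fmt!r}")


def read_well_table(path) -> WellTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return WellTable(df)


def write_well_table(wells: WellTable, path) -> None:
    wells.frame.to_csv(path, sep="\t", index=False)


def read_marker_table(path) -> MarkerTable:
    df = pd.read_csv(path, sep="\t")
    df["gene"] = df["gene"].astype(str)
    return MarkerTable(df)


def write_marker_table(markers: MarkerTable, path) -> None:
    markers.frame.to_csv(path, sep="\t", index=False)


def align(matrix: ExpressionMatrix, wells: WellTable) -> tuple[ExpressionMatrix, WellTable]:
    """Restrict matrix and well table to their common cells, matrix order.

    Dropped identifiers are reported through the ``dehop`` logger.
    Idempotent: aligning already-aligned objects returns them unchanged
    in content.
    """
    common = [c for c in matrix.cells if c in set(wells.cell_ids)]
    if not common:
        raise ValidationError("expression matrix and well table share no cell identifiers")
    n_drop_m = len(matrix.cells) - len(common)
    n_drop_w = len(wells.cell_ids) - len(common)
    if n_drop_m:
        logger.warning("align: dropping %d matrix cells absent from the well table", n_drop_m)
    if n_drop_w:
        logger.warning("align: dropping %d wells absent from the matrix", n_drop_w)
    return matrix.subset_cells(common), wells.subset(common)
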