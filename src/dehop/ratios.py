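r"""Detection-ratio statistics.

For gene A in a pooled library of n_lib single cells, the library
average is

    TPM_bar(A, lib) = (1 / n_lib) * sum_i TPM_i(A)

over wells with status ``cell`` only (empty and qc_fail wells are
excluded).  The per-cell detection ratio is

    phi(A, B) = TPM(A, B) / TPM_bar(A, lib)

and phi_bar(A, T) is its mean over the cells of type T, which equals
TPM_bar(A, T) / TPM_bar(A, lib).  For a gene not natively expressed
in type T, phi_bar(A, T) estimates the index-hopping rate: the
fraction of the gene's library-average expression misassigned to each
cell.  Ratios of genes with zero library average are undefined and
masked, never emitted as numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, ValidationError, WellTable


def _cells_in_scope(wells: WellTable, pool_id=None) -> pd.Index:
    ids = wells.ids_with_status("cell", pool_id=pool_id)
    if len(ids) == 0:
        raise ValidationError("no wells with status=cell in scope")
    return ids


def library_average(
    matrix: ExpressionMatrix, wells: WellTable, pool_id=None
) -> np.ndarray:
    """Per-gene mean TPM over single-cell wells (the library average)."""
    ids = _cells_in_scope(wells, pool_id)
    sub = matrix.subset_cells(ids)
    return sub.values.mean(axis=1)


def type_average(
    matrix: ExpressionMatrix, wells: WellTable, cell_type, pool_id=None
) -> np.ndarray:
    """Per-gene mean TPM over the cells of one type."""
    ids = wells.ids_of_type(cell_type, pool_id=pool_id)
    if len(ids) == 0:
        raise ValidationError(f"unknown or absent cell type {cell_type!r}")
    return matrix.subset_cells(ids).values.mean(axis=1)


def empty_well_average(
    matrix: ExpressionMatrix, wells: WellTable, pool_id=None
) -> np.ndarray:
    """Per-gene mean TPM over empty wells (pure contamination sensors)."""
    ids = wells.ids_with_status("empty", pool_id=pool_id)
    if len(ids) == 0:
        raise ValidationError(
            "no empty wells in scope; skip empty-well diagnostics for this library"
        )
    return matrix.subset_cells(ids).values.mean(axis=1)


@dataclass
class PhiMatrix:
    """Per-gene, per-cell detection ratios with an undefined-gene mask.

    ``defined`` flags genes whose library average is positive; rows of
    undefined genes hold NaN and must not be interpreted.
    """

    genes: pd.Index
    cells: pd.Index
    values: np.ndarray
    defined: np.ndarray
    n_lib: int

    def mean_over_cells(self, cell_ids) -> np.ndarray:
        pos = self.cells.get_indexer(pd.Index(cell_ids))
        if np.any(pos < 0):
            raise ValidationError("phi requested for cells outside the matrix")
        return self.values[:, pos].mean(axis=1)


def phi(matrix: ExpressionMatrix, wells: WellTable, pool_id=None) -> PhiMatrix:
    """Entrywise TPM / library-average for every well column in scope.

    Columns cover all wells of the scope (including empties, so
    empty-well ratios can be inspected); the library average in the
    denominator is computed over single-cell wells only.
    """
    ids = wells.cell_ids if pool_id is None else pd.Index(
        wells.frame.loc[wells.frame["pool_id"] == pool_id, "cell_id"]
    )
    sub = matrix.subset_cells([c for c in ids if c in set(matrix.cells)])
    lib = library_average(matrix, wells, pool_id)
    defined = lib > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = sub.values / lib[:, None]
    vals[~defined, :] = np.nan
    n_lib = len(_cells_in_scope(wells, pool_id))
    return PhiMatrix(sub.genes, sub.cells, vals, defined, n_lib)


@dataclass
class RatioTable:
    """Per-gene library/type averages and mean detection ratios.

    ``phi_bar[T]`` is NaN for genes with zero library average
    (undefined, masked).
    """

    genes: pd.Index
    tpm_lib_avg: np.ndarray
    tpm_type_avg: dict = field(default_factory=dict)
    phi_bar: dict = field(default_factory=dict)
    n_lib: int = 0
    n_type: dict = field(default_factory=dict)
    pool_id: object = None

    @property
    def defined(self) -> np.ndarray:
        return self.tpm_lib_avg > 0

    def phi_bar_series(self, cell_type) -> pd.Series:
        if cell_type not in self.phi_bar:
            raise ValidationError(f"unknown cell type {cell_type!r}")
        return pd.Series(self.phi_bar[cell_type], index=self.genes)

    def to_frame(self) -> pd.DataFrame:
        data = {"tpm_lib_avg": self.tpm_lib_avg}
        for t in self.tpm_type_avg:
            data[f"tpm_avg_{t}"] = self.tpm_type_avg[t]
        for t in self.phi_bar:
            data[f"phi_bar_{t}"] = self.phi_bar[t]
        return pd.DataFrame(data, index=self.genes)


def phi_bar(
    phimatrix: PhiMatrix, wells: WellTable, cell_type, pool_id=None
) -> np.ndarray:
    """Per-gene mean detection ratio over one cell type's cells."""
    ids = wells.ids_of_type(cell_type, pool_id=pool_id)
    if len(ids) == 0:
        raise ValidationError(f"unknown or absent cell type {cell_type!r}")
    return phimatrix.mean_over_cells(ids)


def compute_ratios(
    matrix: ExpressionMatrix, wells: WellTable, pool_id=None, cell_types=None
) -> RatioTable:
    """Build the full ratio table for one library scope.

    phi_bar is computed both as the mean of per-cell phi and as
    type_average / library_average; the two routes are cross-checked
    to catch masking bugs before the table is returned.
    """
    lib = library_average(matrix, wells, pool_id)
    pm = phi(matrix, wells, pool_id)
    if cell_types is None:
        cell_types = (
            wells.cell_types
            if pool_id is None
            else list(
                pd.unique(
                    wells.frame.loc[
                        (wells.frame["pool_id"] == pool_id)
                        & (wells.frame["status"] == "cell"),
                        "cell_type",
                    ]
                )
            )
        )
    table = RatioTable(
        genes=matrix.genes,
        tpm_lib_avg=lib,
        n_lib=pm.n_lib,
        pool_id=pool_id,
    )
    defined = table.defined
    for t in cell_types:
        tavg = type_average(matrix, wells, t, pool_id)
        pb = phi_bar(pm, wells, t, pool_id)
        with np.errstate(divide="ignore", invalid="ignore"):
            pb_direct = np.where(defined, tavg / lib, np.nan)
        if not np.allclose(pb[defined], pb_direct[defined], rtol=1e-9, atol=1e-12):
            raise AssertionError(
                f"phi_bar cross-check failed for type {t!r}: "
                "mean-of-phi and type_avg/lib_avg disagree"
            )
        table.tpm_type_avg[t] = tavg
        table.phi_bar[t] = pb
        table.n_type[t] = len(wells.ids_of_type(t, pool_id=pool_id))
    return table
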