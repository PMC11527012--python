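r"""Subtraction correction for index-hopping contamination.

For a hopping rate r, every single-cell well's TPM for gene A is
replaced by

    max(0, TPM(A, cell) - r * TPM_bar(A, lib))

where the library average is recomputed from the matrix being
corrected, so a rate estimated on one pool can be applied to another.
Negative post-subtraction values are floored at zero (negative TPM is
meaningless downstream and the log2(TPM+1) display convention assumes
non-negativity); the clamp count is surfaced so over-correction is
visible.  Columns are not renormalised to 1e6 afterwards unless
requested: at r << 1 the subtraction perturbs column sums by ~r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .io import ExpressionMatrix, MarkerTable, ValidationError, WellTable
from .ratios import RatioTable, library_average


@dataclass
class CorrectionResult:
    corrected: ExpressionMatrix
    rate: float
    n_clamped: int
    per_gene_subtraction: np.ndarray
    renormalized: bool = False


def correct(
    matrix: ExpressionMatrix,
    wells: WellTable,
    rate: float,
    pool_id=None,
    renormalize: bool = False,
    correct_empty: bool = False,
    force: bool = False,
) -> CorrectionResult:
    """Subtract ``rate`` x per-gene library average from every cell.

    Only wells with status ``cell`` are corrected by default; empty
    and qc_fail wells pass through unmodified (``correct_empty=True``
    also corrects empties).  The output matrix carries a
    ``corrected`` guard flag; correcting an already-corrected matrix
    raises unless ``force=True``, because subtracting twice removes
    twice the contamination.
    """
    if not (0.0 <= rate < 1.0):
        raise ValidationError(f"rate {rate} outside [0, 1)")
    if matrix.corrected and not force:
        raise ValidationError(
            "matrix is already marked as corrected; pass force=True to correct again"
        )
    sub_wells = wells if pool_id is None else wells.restrict_pool(pool_id)
    lib = library_average(matrix, sub_wells)
    subtraction = rate * lib

    statuses = ("cell", "empty") if correct_empty else ("cell",)
    target_ids = sub_wells.frame.loc[
        sub_wells.frame["status"].isin(statuses), "cell_id"
    ]
    col_mask = matrix.cells.isin(set(target_ids))

    values = matrix.values.copy()
    block = values[:, col_mask] - subtraction[:, None]
    n_clamped = int((block < 0).sum())
    np.maximum(block, 0.0, out=block)
    values[:, col_mask] = block
    if renormalize:
        sums = values[:, col_mask].sum(axis=0)
        nz = sums > 0
        values[:, col_mask] = np.where(nz, values[:, col_mask] / sums * 1e6, 0.0)
    corrected = ExpressionMatrix(matrix.genes, matrix.cells, values, corrected=True)
    return CorrectionResult(corrected, float(rate), n_clamped, subtraction, renormalize)


def correction_report(
    before: ExpressionMatrix,
    after: ExpressionMatrix,
    ratios_before: RatioTable,
    ratios_after: RatioTable,
    markers: MarkerTable,
    reference_type,
) -> dict:
    """Per-marker-gene before/after summary of the correction.

    Returns a table of phi_bar and type-average TPM before and after
    for every marker gene, plus paired t-tests (on log2(TPM+1) type
    averages) for self and non-self marker groups.
    """
    if not before.genes.equals(after.genes) or not before.cells.equals(after.cells):
        raise ValidationError("before/after matrices are not aligned")
    rows = []
    for row in markers.frame.itertuples(index=False):
        gene = row.gene
        if gene not in ratios_before.genes:
            continue
        i = ratios_before.genes.get_loc(gene)
        rows.append(
            {
                "gene": gene,
                "marker_type": row.cell_type,
                "is_self": row.cell_type == reference_type,
                "tpm_lib_avg_before": ratios_before.tpm_lib_avg[i],
                "type_avg_before": ratios_before.tpm_type_avg[reference_type][i],
                "type_avg_after": ratios_after.tpm_type_avg[reference_type][i],
                "phi_bar_before": ratios_before.phi_bar[reference_type][i],
                "phi_bar_after": ratios_after.phi_bar[reference_type][i],
            }
        )
    table = pd.DataFrame(rows)
    summary: dict = {"reference_type": reference_type, "table": table}
    if not table.empty:
        table["delta_type_avg"] = table["type_avg_after"] - table["type_avg_before"]
        table["delta_phi_bar"] = table["phi_bar_after"] - table["phi_bar_before"]
        for label, grp in table.groupby("is_self"):
            key = "self_markers" if label else "non_self_markers"
            b = np.log2(grp["type_avg_before"].to_numpy() + 1.0)
            a = np.log2(grp["type_avg_after"].to_numpy() + 1.0)
            if len(grp) >= 2 and np.ptp(b - a) > 0:
                t, p = scipy.stats.ttest_rel(b, a)
                t, p = float(t), float(p)
            else:
                t, p = None, None
            summary[key] = {
                "n_genes": int(len(grp)),
                "mean_phi_bar_before": float(np.nanmean(grp["phi_bar_before"])),
                "mean_phi_bar_after": float(np.nanmean(grp["phi_bar_after"])),
                "paired_t": t,
                "paired_p": p,
            }
    return summary
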