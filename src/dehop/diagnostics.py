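"""Supporting analytics: marker selection, cell distances, summaries.

Everything here is exported as plain tables so the panel computations
(empty-well correlation, side-population scatters, before/after
comparisons, distance distributions) can be asserted numerically;
plotting is left to the caller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .io import ExpressionMatrix, LogTransform, MarkerTable, ValidationError, WellTable
from .ratios import RatioTable, type_average

logger = logging.getLogger("dehop")


def select_markers(
    matrix: ExpressionMatrix,
    wells: WellTable,
    per_type_n: int = 100,
    min_fold: float = 5.0,
    min_tpm: float = 10.0,
    pool_id=None,
) -> MarkerTable:
    """Simple specificity-ranked marker selection.

    For each cell type, genes are ranked by the pseudocounted fold
    ratio (type average + 1) / (max other-type average + 1) and the
    top ``per_type_n`` passing ``min_fold`` and ``min_tpm`` (type
    average) are kept.  This is deliberately plain fold-rank
    filtering -- the estimation pipeline needs specific genes, not
    p-values; externally derived marker tables can be supplied
    instead.
    """
    types = wells.cell_types if pool_id is None else [
        t
        for t in wells.cell_types
        if len(wells.ids_of_type(t, pool_id=pool_id)) > 0
    ]
    if len(types) < 2:
        raise ValidationError("marker selection needs at least 2 cell types")
    avgs = {t: type_average(matrix, wells, t, pool_id) for t in types}
    rows = []
    for t in types:
        others = np.vstack([avgs[u] for u in types if u != t])
        score = (avgs[t] + 1.0) / (others.max(axis=0) + 1.0)
        ok = (score >= min_fold) & (avgs[t] >= min_tpm)
        idx = np.flatnonzero(ok)
        top = idx[np.argsort(-score[idx], kind="stable")][:per_type_n]
        for g in top:
            rows.append(
                {"gene": matrix.genes[g], "cell_type": t, "score": float(score[g])}
            )
    return MarkerTable(pd.DataFrame(rows, columns=["gene", "cell_type", "score"]))


@dataclass
class DistanceMatrix:
    """Symmetric cell-to-cell distances, 1 - Spearman rho on log2(TPM+1)."""

    cells: pd.Index
    values: np.ndarray
    undefined: np.ndarray  # cells with constant profiles (rho undefined)
    metric: str = "1-spearman"

    def within_group(self, cell_ids) -> np.ndarray:
        """Condensed upper-triangle distances among the given cells."""
        pos = self.cells.get_indexer(pd.Index(cell_ids))
        if np.any(pos < 0):
            raise ValidationError("distance requested for unknown cells")
        sub = self.values[np.ix_(pos, pos)]
        iu = np.triu_indices(len(pos), k=1)
        return sub[iu]


def cell_distance(
    matrix: ExpressionMatrix, log_transform: LogTransform | None = None
) -> DistanceMatrix:
    """Pairwise 1 - Spearman correlation of log-transformed profiles.

    Ties receive average ranks; entries lie in [0, 2].  Cells with a
    constant profile have undefined correlation and are flagged (NaN
    rows/columns).
    """
    if matrix.shape[1] < 2:
        raise ValidationError("cell_distance needs at least 2 cells")
    log_transform = log_transform or LogTransform()
    logged = log_transform(matrix.values)
    ranks = scipy.stats.rankdata(logged, axis=0)
    sd = ranks.std(axis=0)
    undefined = sd == 0
    if undefined.any():
        logger.warning("cell_distance: %d constant profiles flagged", undefined.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    dist = 1.0 - rho
    dist[undefined, :] = np.nan
    dist[:, undefined] = np.nan
    np.fill_diagonal(dist, 0.0)
    # enforce exact symmetry against float jitter
    dist = (dist + dist.T) / 2.0
    return DistanceMatrix(matrix.cells, dist, undefined)


def distance_shift(
    before: DistanceMatrix, after: DistanceMatrix, groups: dict
) -> dict:
    """Within-group distance distributions before vs after correction.

    For each group (e.g. cell type -> cell ids): the mean within-group
    distance before and after, their difference, and a two-sample
    Kolmogorov-Smirnov statistic.  Groups with fewer than 2 cells are
    skipped with a warning.
    """
    if not before.cells.equals(after.cells):
        raise ValidationError("before/after distance matrices cover different cells")
    out = {}
    for name, ids in groups.items():
        ids = list(ids)
        if len(ids) < 2:
            logger.warning("distance_shift: group %r has <2 cells; skipped", name)
            continue
        db = before.within_group(ids)
        da = after.within_group(ids)
        if np.array_equal(db, da):
            ks_stat, ks_p = 0.0, 1.0
        else:
            ks = scipy.stats.ks_2samp(db, da)
            ks_stat, ks_p = float(ks.statistic), float(ks.pvalue)
        out[name] = {
            "n_cells": len(ids),
            "n_pairs": len(db),
            "mean_before": float(np.nanmean(db)),
            "mean_after": float(np.nanmean(da)),
            "mean_shift": float(np.nanmean(da) - np.nanmean(db)),
            "ks_statistic": ks_stat,
            "ks_pvalue": ks_p,
        }
    return out


def scatter_tables(
    ratios: RatioTable, markers: MarkerTable | None, reference_type
) -> pd.DataFrame:
    """Per-gene scatter data for side-population style panels.

    One row per gene with a defined ratio: library and reference-type
    averages on the log2(TPM+1) scale, phi_bar, and the marker label
    (empty for unlabelled genes).
    """
    lt = LogTransform()
    defined = ratios.defined
    genes = ratios.genes[defined]
    frame = pd.DataFrame(
        {
            "gene": genes,
            "log2_lib_avg": lt(ratios.tpm_lib_avg[defined]),
            "log2_type_avg": lt(ratios.tpm_type_avg[reference_type][defined]),
            "phi_bar": ratios.phi_bar[reference_type][defined],
        }
    )
    label = pd.Series("", index=pd.Index(genes))
    if markers is not None and len(markers):
        lookup = markers.frame.drop_duplicates("gene").set_index("gene")["cell_type"]
        hit = label.index.intersection(lookup.index)
        label.loc[hit] = lookup.loc[hit].astype(str)
    frame["marker_label"] = label.to_numpy()
    return frame
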