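r"""Index-hopping rate estimators.

Three estimators of the per-library hopping rate r (the fraction of a
gene's library-average expression misassigned to each well):

``rank_tangent``
    Rank all genes increasingly by the reciprocal of their mean
    detection ratio phi_bar in a reference cell type, rescale both
    axes to [0, 1], and take phi_bar at the point where a line of
    slope 1 is tangent to the curve from below.  On the rescaled
    curve that point is argmax_i (x_i - y_i): for a convex
    non-decreasing curve, the support line of slope 1 touches exactly
    where x - y is largest, which is noise-robust and needs no
    numerical differentiation.  Genes whose detection in the
    reference type is dominated by hopping pile up near the
    reciprocal ceiling 1/r, producing the inflection the tangent
    finds.

``side_population_mean``
    The mean phi_bar of "side population" genes: highly expressed
    non-self markers whose detection in the reference type is
    proportional to their library average.  Their average detection
    ratio is, by definition of the contamination model, the hopping
    rate.

``empty_well``
    Empty wells carry no cell, so any signal there is misassignment;
    the robust (median) per-gene ratio of empty-well average to
    library average estimates r, and the Spearman correlation between
    the two averages diagnoses whether contamination tracks library
    expression (the signature of a stochastic hopping process).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .io import ExpressionMatrix, MarkerTable, ValidationError, WellTable
from .ratios import RatioTable, compute_ratios, empty_well_average, library_average

logger = logging.getLogger("dehop")

#: hopping is measurable only on well-expressed genes; ratios of genes
#: below this library-average TPM are dominated by sampling noise
DEFAULT_MIN_LIB_TPM = 10.0

#: phi_bar cutoff for side-population membership ("consistently below 1%")
DEFAULT_SIDE_THRESHOLD = 0.01


@dataclass
class RankCurve:
    """Rescaled rank curve of reciprocal detection ratios."""

    genes: np.ndarray
    phi_bar: np.ndarray
    x: np.ndarray
    y: np.ndarray
    excluded_genes: np.ndarray
    n_no_detection: int
    y_transform: str
    reference_type: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.genes,
                "phi_bar": self.phi_bar,
                "reciprocal": 1.0 / self.phi_bar,
                "x": self.x,
                "y": self.y,
            }
        )


@dataclass
class GenePartition:
    """Gene classes induced by the rank-curve threshold."""

    reference_expressed: np.ndarray
    hopping_attributed: np.ndarray
    no_detection: np.ndarray


@dataclass
class HopEstimate:
    rate: float
    method: str
    reference_type: str | None = None
    pool_id: object = None
    y_transform: str | None = None
    tangent_gene: str | None = None
    tangent_rank: int | None = None
    partition: GenePartition | None = None
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.rate < 1.0):
            raise ValidationError(f"estimated rate {self.rate} outside [0, 1)")

    def to_dict(self) -> dict:
        d = {
            "rate": float(self.rate),
            "method": self.method,
            "reference_type": self.reference_type,
            "pool_id": self.pool_id,
            "y_transform": self.y_transform,
            "tangent_gene": self.tangent_gene,
            "tangent_rank": self.tangent_rank,
        }
        d.update({k: v for k, v in self.details.items() if not k.startswith("_")})
        return d


@dataclass
class SidePopulation:
    genes: np.ndarray
    threshold: float
    min_lib_tpm: float
    donor_types: list
    reference_type: str

    def __len__(self) -> int:
        return len(self.genes)


def build_rank_curve(
    ratios: RatioTable, reference_type, y_transform: str = "linear"
) -> RankCurve:
    """Sort genes increasingly by 1/phi_bar and rescale to the unit square.

    Genes with phi_bar = 0 (no detection in the reference type) or an
    undefined ratio are excluded and recorded.  Sort ties are broken
    by gene id for determinism.  ``y_transform='log'`` rescales
    log(1/phi_bar) instead, for curves whose reciprocals span orders
    of magnitude.
    """
    if y_transform not in ("linear", "log"):
        raise ValidationError(f"unknown y_transform {y_transform!r}")
    pb = ratios.phi_bar_series(reference_type)
    usable = pb.notna() & (pb > 0)
    excluded = pb.index[~usable].to_numpy()
    n_no_detection = int(((pb == 0) & pb.notna()).sum())
    pb = pb[usable]
    if len(pb) < 3:
        raise ValidationError(
            f"only {len(pb)} genes with phi_bar > 0 in {reference_type!r}; "
            "need at least 3 to build a rank curve"
        )
    v = 1.0 / pb.to_numpy()
    order = np.lexsort((pb.index.to_numpy(), v))
    v = v[order]
    genes = pb.index.to_numpy()[order]
    pb_sorted = pb.to_numpy()[order]
    vv = np.log(v) if y_transform == "log" else v
    span = vv[-1] - vv[0]
    if span <= 0:
        raise ValidationError(
            "degenerate rank curve: all reciprocal detection ratios equal"
        )
    n = len(v)
    x = np.arange(n, dtype=float) / (n - 1)
    y = (vv - vv[0]) / span
    return RankCurve(
        genes, pb_sorted, x, y, excluded, n_no_detection, y_transform, reference_type
    )


def tangent_point(curve: RankCurve) -> tuple[int, str]:
    """Index and gene where a slope-1 line is tangent from below.

    Computed as argmax(x - y); ties broken by the largest rank.  A
    flat curve (all gaps ~0) is reported with a warning.
    """
    gaps = curve.x - curve.y
    best = gaps.max()
    if best <= 1e-12:
        logger.warning("tangent_point: flat rank curve (y = x); returning last point")
    idx = int(np.flatnonzero(gaps >= best - 1e-15)[-1])
    return idx, str(curve.genes[idx])


def tangent_point_slope_scan(curve: RankCurve) -> tuple[int, str]:
    """Alternative tangent locator by numerical slope scanning.

    Finds the first point (from the high-rank end) where the local
    finite-difference slope drops below 1.  Retained for comparison
    with the argmax(x - y) form; noisier on rough curves.
    """
    dx = np.diff(curve.x)
    dy = np.diff(curve.y)
    slopes = dy / dx
    below = np.flatnonzero(slopes <= 1.0)
    idx = int(below[-1] + 1) if len(below) else 0
    return idx, str(curve.genes[idx])


def estimate_rate_rank(
    ratios: RatioTable, reference_type, y_transform: str = "linear"
) -> HopEstimate:
    """Rank-curve tangent estimate of the hopping rate.

    The rate is phi_bar of the tangent gene.  Genes ranked below the
    tangent are classified as predominantly reference-type-expressed;
    genes above it as detected, at least in part, through index
    hopping.
    """
    curve = build_rank_curve(ratios, reference_type, y_transform)
    idx, gene = tangent_point(curve)
    rate = float(curve.phi_bar[idx])
    if rate >= 1.0:
        raise ValidationError(
            f"rank tangent landed at phi_bar={rate:.3g} (>= 1): the curve has no "
            "hopping inflection; try the side_population or empty_well estimators"
        )
    pb = ratios.phi_bar_series(reference_type)
    no_det = pb.index[(pb == 0) & pb.notna()].to_numpy()
    partition = GenePartition(
        reference_expressed=curve.genes[:idx],
        hopping_attributed=curve.genes[idx:],
        no_detection=no_det,
    )
    return HopEstimate(
        rate=rate,
        method="rank_tangent",
        reference_type=reference_type,
        pool_id=ratios.pool_id,
        y_transform=y_transform,
        tangent_gene=gene,
        tangent_rank=idx,
        partition=partition,
        details={
            "n_genes_on_curve": int(len(curve.genes)),
            "n_no_detection": curve.n_no_detection,
            "_curve": curve,
        },
    )


def identify_side_population(
    ratios: RatioTable,
    markers: MarkerTable,
    reference_type,
    threshold: float = DEFAULT_SIDE_THRESHOLD,
    min_lib_tpm: float = DEFAULT_MIN_LIB_TPM,
) -> SidePopulation:
    """Non-self marker genes whose detection looks like pure hopping.

    Members are markers of donor (non-reference) types with library
    average >= ``min_lib_tpm`` and phi_bar in the reference type below
    ``threshold``.  Non-specific markers with true residual expression
    in the reference type (phi_bar above the threshold) are excluded.
    """
    donor_types = [t for t in markers.cell_types if t != reference_type]
    if not donor_types:
        raise ValidationError("marker table contains no non-reference donor types")
    non_self = markers.non_self_genes(reference_type)
    pb = ratios.phi_bar_series(reference_type)
    lib = pd.Series(ratios.tpm_lib_avg, index=ratios.genes)
    present = non_self[non_self.isin(pb.index)]
    pbns = pb[present]
    keep = (lib[present] >= min_lib_tpm) & pbns.notna() & (pbns < threshold)
    genes = present[keep.to_numpy()].to_numpy()
    if len(genes) == 0:
        logger.warning(
            "identify_side_population: no qualifying genes (threshold=%g, min_lib_tpm=%g)",
            threshold,
            min_lib_tpm,
        )
    return SidePopulation(genes, threshold, min_lib_tpm, donor_types, reference_type)


def estimate_rate_side_population(
    ratios: RatioTable, side: SidePopulation, reference_type=None
) -> HopEstimate:
    """Mean phi_bar over side-population genes as the hopping rate."""
    reference_type = reference_type or side.reference_type
    if len(side) == 0:
        raise ValidationError("empty side population; cannot estimate a rate")
    pb = ratios.phi_bar_series(reference_type)
    vals = pb[pd.Index(side.genes)].to_numpy()
    return HopEstimate(
        rate=float(np.mean(vals)),
        method="side_population_mean",
        reference_type=reference_type,
        pool_id=ratios.pool_id,
        details={
            "n_side_genes": int(len(side)),
            "threshold": side.threshold,
            "min_lib_tpm": side.min_lib_tpm,
            "phi_bar_min": float(vals.min()),
            "phi_bar_max": float(vals.max()),
        },
    )


def estimate_rate_empty_wells(
    matrix: ExpressionMatrix,
    wells: WellTable,
    pool_id=None,
    min_lib_tpm: float = DEFAULT_MIN_LIB_TPM,
) -> HopEstimate:
    """Median empty-to-library expression ratio as the hopping rate.

    Also reports the Spearman correlation between empty-well and
    library averages over well-expressed genes; a positive correlation
    indicates contamination proportional to library expression.
    """
    lib = library_average(matrix, wells, pool_id)
    empty = empty_well_average(matrix, wells, pool_id)
    mask = lib >= min_lib_tpm
    if not mask.any():
        raise ValidationError(
            f"no genes with library average >= {min_lib_tpm} TPM for the "
            "empty-well estimator"
        )
    ratios_ = empty[mask] / lib[mask]
    rate = float(np.median(ratios_))
    if np.ptp(empty[mask]) == 0 or np.ptp(lib[mask]) == 0:
        corr = None
        logger.warning("empty-well correlation undefined (constant averages)")
    else:
        corr = float(scipy.stats.spearmanr(empty[mask], lib[mask]).statistic)
    n_empty = len(wells.ids_with_status("empty", pool_id=pool_id))
    return HopEstimate(
        rate=rate,
        method="empty_well",
        pool_id=pool_id,
        details={
            "spearman_empty_vs_library": corr,
            "n_empty_wells": n_empty,
            "n_genes_used": int(mask.sum()),
            "min_lib_tpm": min_lib_tpm,
        },
    )


def estimate_rates(
    matrix: ExpressionMatrix,
    wells: WellTable,
    markers: MarkerTable | None = None,
    reference_type=None,
    methods=("rank", "side", "empty"),
    scope: str = "pool",
    y_transform: str = "linear",
    threshold: float = DEFAULT_SIDE_THRESHOLD,
    min_lib_tpm: float = DEFAULT_MIN_LIB_TPM,
) -> list[HopEstimate]:
    """Run the requested estimators over each pool (or globally).

    The reference type defaults to the most abundant cell type in
    each scope.  The ``side`` method requires a marker table; the
    ``empty`` method requires empty wells and is skipped with a
    warning if a scope has none.
    """
    if scope not in ("pool", "global"):
        raise ValidationError(f"unknown scope {scope!r}")
    if "side" in methods and markers is None:
        raise ValidationError("the side-population method requires a marker table")
    pools = wells.pools if scope == "pool" else [None]
    estimates: list[HopEstimate] = []
    for pool in pools:
        ref = reference_type or most_abundant_type(wells, pool)
        ratios = compute_ratios(matrix, wells, pool_id=pool)
        if "rank" in methods:
            estimates.append(estimate_rate_rank(ratios, ref, y_transform))
        if "side" in methods:
            side = identify_side_population(
                ratios, markers, ref, threshold=threshold, min_lib_tpm=min_lib_tpm
            )
            estimates.append(estimate_rate_side_population(ratios, side))
        if "empty" in methods:
            n_empty = len(wells.ids_with_status("empty", pool_id=pool))
            if n_empty == 0:
                logger.warning("no empty wells in scope %r; empty-well method skipped", pool)
            else:
                estimates.append(
                    estimate_rate_empty_wells(matrix, wells, pool, min_lib_tpm)
                )
    return estimates


def most_abundant_type(wells: WellTable, pool_id=None) -> str:
    """Default reference type: the most abundant cell type in scope."""
    df = wells.frame
    mask = df["status"] == "cell"
    if pool_id is not None:
        mask &= df["pool_id"] == pool_id
    counts = df.loc[mask, "cell_type"].value_counts()
    if counts.empty:
        raise ValidationError("no cells in scope")
    return str(counts.index[0])
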