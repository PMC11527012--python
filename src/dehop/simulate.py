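r"""Synthetic pooled-plate scRNA-seq libraries with known hopping.

The generator emulates a deeply sequenced, plate-based (Smart-seq2
style) experiment: one or more 16 x 24 dual-indexed pools holding a
few transcriptionally distinct cell types, a handful of empty wells,
some QC-failed wells, and index-hopping contamination at a known rate
so every estimator and the correction can be verified by parameter
recovery.

Clean expression
----------------
Each gene gets a log-normal baseline level.  Marker genes are
expressed only in their own type, elevated ``marker_effect``-fold
(set ``leaky_markers`` > 0 for non-specific markers with residual
expression elsewhere).  Every other gene is expressed in a random
subset of types (probability ``p_expressed`` per type), with a
per-type log2-normal fold factor of sd ``type_sd`` -- real cell types
differ by orders of magnitude in per-gene expression, and this spread
is what gives the reference type a realistic continuum of detection
ratios between fully-self and fully-non-self genes.  Per-cell
multiplicative noise is applied and each sequenced column is scaled
to sum to 1e6 (TPM).

Contamination models
--------------------
``global``
    Every well in a pool receives, for each gene, ``rate`` times the
    pool's *observed* library-average expression of that gene
    (equivalently ``rate / (1 - rate)`` times the clean library
    average).  Defined this way, the hopped fraction of the library
    average that the estimators measure -- and that the correction
    subtracts -- is exactly ``rate``.

``pairwise``
    Each recipient well receives ``rate`` times the summed expression
    of same-pool donor cells sharing its i7 or i5 index, divided by
    the library size, so contamination grows with the number of
    index-sharing donors and dual-class recipients receive more than
    single-class ones.  The realised library-wide contamination
    fraction is reported as ``effective_rate``.

Hopped reads are few, so their sampling variability is substantial;
by default contamination is multiplied by a per-entry gamma noise
field whose shape equals the expected number of hopped reads (from
``reads_per_cell``, default 3e6).  Set ``reads_per_cell=None`` for
the deterministic expected-value model, under which the global-model
identities (empty wells exactly ``rate`` x library average, non-self
phi_bar exactly ``rate``) hold exactly.

The noise field and the clean matrix are frozen per (config, seed);
:func:`regenerate` rebuilds the contamination at a new rate on the
same realisation, so rate-monotonicity can be tested without
resampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, MarkerTable, ValidationError, WellTable

DEFAULT_CELL_TYPES = (("MC", 120, 50), ("DC", 80, 50), ("HC", 60, 50), ("KC", 60, 50))


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for one simulated experiment."""

    n_genes: int = 5000
    cell_types: tuple = DEFAULT_CELL_TYPES
    marker_effect: float = 50.0
    leaky_markers: float = 0.0
    base_expression: tuple = (4.2, 1.5)  # (mean, sd) of log TPM-scale baseline
    type_sd: float = 2.5  # log2 sd of per-type expression factors
    p_expressed: float = 0.3  # per-type expression probability, non-marker genes
    noise: float = 0.5  # per-cell multiplicative log-normal sd
    stage_sd: float = 1.0  # log2 sd of developmental-stage gene loadings
    background_rate: float = 1e-4  # sporadic technical background, fraction of lib avg
    background_dispersion: float = 2.0  # log-normal sd of per-entry background rate
    n_i7: int = 16
    n_i5: int = 24
    n_pools: int = 1
    n_empty: int = 16
    n_qc_fail: int = 8
    rate: float = 0.0065
    model: str = "global"
    reads_per_cell: float | None = 3e6
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.rate < 1.0):
            raise ValidationError(f"rate {self.rate} outside [0, 1)")
        if self.model not in ("global", "pairwise"):
            raise ValidationError(f"unknown contamination model {self.model!r}")
        n_cells = sum(n for _, n, _ in self.cell_types)
        capacity = self.n_i7 * self.n_i5 * self.n_pools
        if n_cells + self.n_empty + self.n_qc_fail > capacity:
            raise ValidationError(
                f"layout infeasible: {n_cells} cells + {self.n_empty} empty + "
                f"{self.n_qc_fail} qc wells exceed {capacity} wells"
            )
        n_markers = sum(m for _, _, m in self.cell_types)
        if n_markers > self.n_genes // 3:
            raise ValidationError(
                "marker genes are drawn from the top third of baseline "
                f"expression; {n_markers} markers exceed n_genes//3 = {self.n_genes // 3}"
            )


@dataclass
class SimTruth:
    """A simulated library together with its ground truth."""

    config: SimConfig
    true_rate: float
    effective_rate: float
    empty_effective_rate: float
    markers: MarkerTable
    clean: ExpressionMatrix
    contaminated: ExpressionMatrix
    wells: WellTable
    # rate-independent expected contamination pattern and frozen noise
    # field, kept so regenerate() can rescale without resampling
    base_pattern: np.ndarray = field(repr=False, default=None)
    eta: np.ndarray = field(repr=False, default=None)

    def truth_dict(self) -> dict:
        return {
            "true_rate": self.true_rate,
            "effective_rate": self.effective_rate,
            "empty_effective_rate": self.empty_effective_rate,
            "model": self.config.model,
            "seed": self.config.seed,
            "n_genes": self.config.n_genes,
            "n_cells": int((self.wells.frame["status"] == "cell").sum()),
        }


def _split_counts(total: int, parts: int) -> list[int]:
    base, extra = divmod(total, parts)
    return [base + (i < extra) for i in range(parts)]


def _place_type_block(rng, occupied: np.ndarray, n_cells: int) -> list[tuple[int, int]]:
    """Pick a random row x column sub-grid and fill it with cells.

    Confining each type to a sub-grid (rather than scattering it over
    the whole plate) reproduces the mixed-plate geometry in which a
    reference cell can have dual, single, or no index-sharing with a
    donor type.  The sub-grid is grown until it holds enough free
    wells.
    """
    n_i7, n_i5 = occupied.shape
    if n_cells == 0:
        return []
    target = math.ceil(1.6 * n_cells)
    n_rows = min(n_i7, max(1, math.ceil(math.sqrt(target * n_i7 / n_i5))))
    n_cols = min(n_i5, max(1, math.ceil(target / n_rows)))
    rows = set(rng.choice(n_i7, size=n_rows, replace=False).tolist())
    cols = set(rng.choice(n_i5, size=n_cols, replace=False).tolist())

    def free_wells():
        return [
            (r, c) for r in sorted(rows) for c in sorted(cols) if not occupied[r, c]
        ]

    grow_row = True
    while len(free_wells()) < n_cells:
        can_row = len(rows) < n_i7
        can_col = len(cols) < n_i5
        if not (can_row or can_col):
            raise ValidationError("layout infeasible: plate full")
        if (grow_row and can_row) or not can_col:
            rows.add(int(rng.choice([r for r in range(n_i7) if r not in rows])))
        else:
            cols.add(int(rng.choice([c for c in range(n_i5) if c not in cols])))
        grow_row = not grow_row
    free = free_wells()
    picked = rng.choice(len(free), size=n_cells, replace=False)
    chosen = [free[i] for i in sorted(picked.tolist())]
    for r, c in chosen:
        occupied[r, c] = True
    return chosen


def _build_wells(config: SimConfig, rng) -> pd.DataFrame:
    rows = []
    labels = [t for t, _, _ in config.cell_types]
    per_pool = {
        t: _split_counts(n, config.n_pools) for t, n, _ in config.cell_types
    }
    empty_pp = _split_counts(config.n_empty, config.n_pools)
    qc_pp = _split_counts(config.n_qc_fail, config.n_pools)
    for p in range(config.n_pools):
        pool = f"pool{p + 1}"
        occupied = np.zeros((config.n_i7, config.n_i5), dtype=bool)
        for t in labels:
            for r, c in _place_type_block(rng, occupied, per_pool[t][p]):
                rows.append((pool, r, c, "cell", t))
        free = np.argwhere(~occupied)
        n_misc = empty_pp[p] + qc_pp[p]
        idx = rng.choice(len(free), size=n_misc, replace=False)
        for k, i in enumerate(idx.tolist()):
            r, c = map(int, free[i])
            occupied[r, c] = True
            status = "empty" if k < empty_pp[p] else "qc_fail"
            rows.append((pool, r, c, status, None))
    df = pd.DataFrame(rows, columns=["pool_id", "i7", "i5", "status", "cell_type"])
    df = df.sort_values(["pool_id", "i7", "i5"]).reset_index(drop=True)
    df["cell_id"] = [
        f"{p}_r{r:02d}_c{c:02d}" for p, r, c in zip(df["pool_id"], df["i7"], df["i5"])
    ]
    df["i7_index"] = "i7_" + df["i7"].astype(str).str.zfill(2)
    df["i5_index"] = "i5_" + df["i5"].astype(str).str.zfill(2)
    return df[["cell_id", "pool_id", "i7_index", "i5_index", "status", "cell_type"]]


def _type_profiles(config: SimConfig, rng) -> tuple[np.ndarray, MarkerTable]:
    """Per-type mean expression templates (genes x types) and markers."""
    n_types = len(config.cell_types)
    labels = [t for t, _, _ in config.cell_types]
    baseline = rng.lognormal(*config.base_expression, size=config.n_genes)
    # signature genes are the *top* highly and specifically expressed
    # genes of each type, so marker genes are drawn from the upper
    # baseline-expression tier rather than uniformly
    top_tier = np.argsort(-baseline, kind="stable")[: max(1, config.n_genes // 3)]
    perm = top_tier[rng.permutation(len(top_tier))]
    marker_rows = []
    marker_of = np.full(config.n_genes, -1)
    pos = 0
    for ti, (label, _, n_markers) in enumerate(config.cell_types):
        for g in perm[pos : pos + n_markers]:
            marker_of[g] = ti
            marker_rows.append({"gene": f"G{g:05d}", "cell_type": label, "score": 1.0})
        pos += n_markers

    profiles = np.zeros((config.n_genes, n_types))
    non_marker = marker_of < 0
    n_free = int(non_marker.sum())
    on = rng.random((n_free, n_types)) < config.p_expressed
    silent = ~on.any(axis=1)
    on[silent, rng.integers(0, n_types, size=int(silent.sum()))] = True
    factors = np.exp2(rng.normal(0.0, config.type_sd, size=(n_free, n_types))) * on
    profiles[non_marker] = baseline[non_marker, None] * factors
    for ti in range(n_types):
        is_m = marker_of == ti
        profiles[is_m, :] = baseline[is_m, None] * config.leaky_markers
        profiles[is_m, ti] = baseline[is_m] * config.marker_effect
    markers = MarkerTable(pd.DataFrame(marker_rows))
    return profiles, markers


def _clean_matrix(
    config: SimConfig, wells_df: pd.DataFrame, profiles: np.ndarray, rng
) -> np.ndarray:
    labels = [t for t, _, _ in config.cell_types]
    type_index = {t: i for i, t in enumerate(labels)}
    n_wells = len(wells_df)
    values = np.zeros((config.n_genes, n_wells))
    # within-type biological heterogeneity: each cell sits at a random
    # developmental stage; stage-loaded genes shift smoothly with it
    # (the sampled animals span embryonic to postnatal ages)
    stage_loading = rng.normal(0.0, config.stage_sd, size=config.n_genes)
    for j, row in enumerate(wells_df.itertuples(index=False)):
        if row.status == "empty":
            continue
        if row.status == "qc_fail":
            # degraded well: random type template, double noise; scale is
            # irrelevant after TPM normalisation and qc wells are excluded
            # from every downstream statistic anyway
            ti = int(rng.integers(0, len(labels)))
            sd = 2.0 * config.noise
        else:
            ti = type_index[row.cell_type]
            sd = config.noise
        stage = rng.uniform(-1.0, 1.0)
        col = (
            profiles[:, ti]
            * np.exp2(stage * stage_loading)
            * rng.lognormal(0.0, sd, size=config.n_genes)
        )
        total = col.sum()
        values[:, j] = col / total * 1e6 if total > 0 else 0.0
    return values


def _add_background(
    config: SimConfig, wells_df: pd.DataFrame, values: np.ndarray, rng
) -> None:
    """Sporadic technical background detection, in place.

    Sequenced libraries show scattered low-level reads at genes a cell
    does not express (ambient molecules, barcode and mapping errors)
    even without index hopping.  Modelled as overdispersed Poisson
    reads proportional to the pool's library-average composition,
    *uncorrelated* across wells -- unlike hopping, whose fill pattern
    is shared.  Only present in the read-sampling regime; the
    expected-value model (``reads_per_cell=None``) stays background
    free so its analytic identities hold exactly.
    """
    if not config.reads_per_cell or config.background_rate <= 0:
        return
    depth = config.reads_per_cell / 1e6
    for pool in pd.unique(wells_df["pool_id"]):
        in_pool = (wells_df["pool_id"] == pool).to_numpy()
        is_cell = in_pool & (wells_df["status"] == "cell").to_numpy()
        lib_bio = values[:, is_cell].mean(axis=1)
        n_pool = int(in_pool.sum())
        sd = config.background_dispersion
        eps = rng.lognormal(-0.5 * sd**2, sd, size=(len(lib_bio), n_pool))
        lam = config.background_rate * lib_bio[:, None] * depth * eps
        values[:, in_pool] += rng.poisson(lam) / depth


def _contamination_inputs(
    config: SimConfig, wells_df: pd.DataFrame, clean: np.ndarray, rng
) -> tuple[np.ndarray, np.ndarray]:
    """Rate-independent contamination pattern and frozen noise field.

    The pattern is, per well column, the per-gene quantity that the
    model multiplies by its rate factor: the pool's clean library
    average (global) or the index-sharing donor sum over the library
    size (pairwise).  The gamma noise shape is the expected number of
    hopped reads per entry at the configured rate.
    """
    n_genes, n_wells = clean.shape
    pattern = np.zeros_like(clean)
    for pool in pd.unique(wells_df["pool_id"]):
        in_pool = (wells_df["pool_id"] == pool).to_numpy()
        is_cell = in_pool & (wells_df["status"] == "cell").to_numpy()
        n_lib = int(is_cell.sum())
        lib_clean = clean[:, is_cell].mean(axis=1)
        if config.model == "global":
            pattern[:, in_pool] = lib_clean[:, None]
        else:
            i7 = wells_df["i7_index"].to_numpy()
            i5 = wells_df["i5_index"].to_numpy()
            pool_idx = np.flatnonzero(in_pool)
            cell_idx = np.flatnonzero(is_cell)
            share = (
                (i7[pool_idx][:, None] == i7[cell_idx][None, :])
                | (i5[pool_idx][:, None] == i5[cell_idx][None, :])
            ) & (pool_idx[:, None] != cell_idx[None, :])
            pattern[:, pool_idx] = clean[:, cell_idx] @ share.T.astype(float) / n_lib
    if config.reads_per_cell and config.rate > 0:
        # expected hopped reads per entry at the configured rate; the
        # realised read count is Poisson, so entries with no hopped
        # read are exactly zero, as in real data
        lam = config.rate * pattern * config.reads_per_cell / 1e6
        eta = np.ones_like(pattern)
        nz = lam > 0
        eta[nz] = rng.poisson(lam[nz]) / lam[nz]
    else:
        eta = np.ones_like(pattern)
    return pattern, eta


def _rate_factor(rate: float, model: str) -> float:
    # global contamination is rate x *observed* library average, i.e.
    # rate/(1-rate) x clean library average (fixed point)
    return rate / (1.0 - rate) if model == "global" else rate


def _effective_rate(
    config: SimConfig, wells_df: pd.DataFrame, clean: np.ndarray, add_expected: np.ndarray,
    rate: float, status: str = "cell",
) -> float:
    """Realised median hopped fraction of the observed library average.

    Measured over the wells of the given status; under the pairwise
    model, empty wells tend to sit in sparser plate regions and
    receive less than single-cell wells.
    """
    if config.model == "global":
        return rate
    fracs = []
    for pool in pd.unique(wells_df["pool_id"]):
        in_pool = (wells_df["pool_id"] == pool).to_numpy()
        is_cell = in_pool & (wells_df["status"] == "cell").to_numpy()
        target = in_pool & (wells_df["status"] == status).to_numpy()
        if not target.any():
            continue
        lib_obs = (clean[:, is_cell] + add_expected[:, is_cell]).mean(axis=1)
        mean_add = add_expected[:, target].mean(axis=1)
        mask = lib_obs >= 10.0
        if mask.any():
            fracs.append(np.median(mean_add[mask] / lib_obs[mask]))
    return float(np.mean(fracs)) if fracs else 0.0


def simulate(config: SimConfig | None = None, **overrides) -> SimTruth:
    """Generate a library with known contamination.

    Deterministic given (config, seed): identical inputs give
    bit-identical outputs.
    """
    if config is None:
        config = SimConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    config.validate()
    root = np.random.default_rng(config.seed)
    rng_layout, rng_genes, rng_cells, rng_bg, rng_contam = root.spawn(5)

    wells_df = _build_wells(config, rng_layout)
    profiles, markers = _type_profiles(config, rng_genes)
    clean_values = _clean_matrix(config, wells_df, profiles, rng_cells)
    _add_background(config, wells_df, clean_values, rng_bg)
    pattern, eta = _contamination_inputs(config, wells_df, clean_values, rng_contam)

    genes = pd.Index([f"G{g:05d}" for g in range(config.n_genes)])
    cells = pd.Index(wells_df["cell_id"])
    factor = _rate_factor(config.rate, config.model)
    contaminated_values = clean_values + factor * pattern * eta

    truth = SimTruth(
        config=config,
        true_rate=config.rate,
        effective_rate=_effective_rate(
            config, wells_df, clean_values, factor * pattern, config.rate
        ),
        empty_effective_rate=_effective_rate(
            config, wells_df, clean_values, factor * pattern, config.rate, "empty"
        ),
        markers=markers,
        clean=ExpressionMatrix(genes, cells, clean_values),
        contaminated=ExpressionMatrix(genes, cells, contaminated_values),
        wells=WellTable(wells_df),
        base_pattern=pattern,
        eta=eta,
    )
    return truth


def regenerate(truth: SimTruth, new_rate: float) -> SimTruth:
    """Same clean matrix and noise realisation, new contamination rate.

    Contamination scales exactly linearly with the model's rate factor
    (``new_rate/(1-new_rate)`` for global, ``new_rate`` for pairwise),
    which makes estimator-monotonicity testable without resampling.
    """
    if not (0.0 <= new_rate < 1.0):
        raise ValidationError(f"rate {new_rate} outside [0, 1)")
    config = replace(truth.config, rate=new_rate)
    factor = _rate_factor(new_rate, config.model)
    contaminated_values = truth.clean.values + factor * truth.base_pattern * truth.eta
    return SimTruth(
        config=config,
        true_rate=new_rate,
        effective_rate=_effective_rate(
            config, truth.wells.frame, truth.clean.values, factor * truth.base_pattern,
            new_rate,
        ),
        empty_effective_rate=_effective_rate(
            config, truth.wells.frame, truth.clean.values, factor * truth.base_pattern,
            new_rate, "empty",
        ),
        markers=truth.markers,
        clean=truth.clean,
        contaminated=ExpressionMatrix(
            truth.clean.genes, truth.clean.cells, contaminated_values
        ),
        wells=truth.wells,
        base_pattern=truth.base_pattern,
        eta=truth.eta,
    )
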