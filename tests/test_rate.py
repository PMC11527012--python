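import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dehop import (
    ExpressionMatrix,
    RankCurve,
    ValidationError,
    build_rank_curve,
    compute_ratios,
    estimate_rate_empty_wells,
    estimate_rate_rank,
    estimate_rate_side_population,
    estimate_rates,
    identify_side_population,
    most_abundant_type,
    simulate,
    tangent_point,
)
from dehop.ratios import RatioTable
from dehop.rate import tangent_point_slope_scan

from conftest import small_config
from test_ratios import wells_of


def ratio_table(phi_bars, lib_avgs=None, reference="MC"):
    genes = pd.Index([f"g{i}" for i in range(len(phi_bars))])
    pb = np.asarray(phi_bars, dtype=float)
    lib = np.asarray(
        lib_avgs if lib_avgs is not None else np.full(len(pb), 100.0), dtype=float
    )
    return RatioTable(
        genes=genes,
        tpm_lib_avg=lib,
        tpm_type_avg={reference: pb * lib},
        phi_bar={reference: pb},
        n_lib=10,
        n_type={reference: 5},
    )


def curve_from_xy(x, y):
    n = len(x)
    genes = np.array([f"g{i}" for i in range(n)])
    return RankCurve(
        genes=genes,
        phi_bar=np.linspace(1.0, 0.1, n),
        x=np.asarray(x, float),
        y=np.asarray(y, float),
        excluded_genes=np.array([]),
        n_no_detection=0,
        y_transform="linear",
        reference_type="MC",
    )


def brute_force_tangent(curve):
    """All slope-1 support lines from below; touching point, last if tied."""
    x, y = curve.x, curve.y
    best_idx, best_offset = None, None
    for i in range(len(x)):
        offset = y[i] - x[i]  # line y = x + offset through point i
        if np.all(y >= x + offset - 1e-12):
            if best_offset is None or offset < best_offset - 1e-12 or (
                abs(offset - best_offset) <= 1e-12 and i > best_idx
            ):
                best_idx, best_offset = i, offset
    return best_idx


class TestRankCurve:
    def test_three_gene_example(self):
        rt = ratio_table([2.0, 1.0, 0.5])
        curve = build_rank_curve(rt, "MC")
        assert list(curve.genes) == ["g0", "g1", "g2"]  # increasing by 1/phi_bar
        np.testing.assert_allclose(curve.x, [0.0, 0.5, 1.0])
        np.testing.assert_allclose(curve.y, [0.0, 1 / 3, 1.0])

    def test_zero_phi_bar_gene_excluded_and_recorded(self):
        rt = ratio_table([2.0, 0.0, 1.0, 0.5])
        curve = build_rank_curve(rt, "MC")
        assert "g1" in curve.excluded_genes
        assert curve.n_no_detection == 1
        assert len(curve.genes) == 3

    def test_undefined_ratio_excluded(self):
        rt = ratio_table([2.0, 1.0, 0.5, np.nan])
        curve = build_rank_curve(rt, "MC")
        assert "g3" in curve.excluded_genes

    def test_too_few_genes_error(self):
        with pytest.raises(ValidationError, match="at least 3"):
            build_rank_curve(ratio_table([1.0, 0.0, 0.0]), "MC")

    def test_degenerate_flat_curve_error(self):
        with pytest.raises(ValidationError, match="degenerate"):
            build_rank_curve(ratio_table([1.0, 1.0, 1.0]), "MC")

    def test_sort_ties_broken_by_gene_id(self):
        rt = ratio_table([1.0, 0.5, 1.0, 2.0])
        curve = build_rank_curve(rt, "MC")
        assert list(curve.genes) == ["g3", "g0", "g2", "g1"]

    def test_large_random_sort_matches_independent_sort(self):
        rng = np.random.default_rng(7)
        pb = rng.lognormal(-2, 1.5, 1000)
        curve = build_rank_curve(ratio_table(pb), "MC")
        recips = 1.0 / pb
        expected = [f"g{i}" for i in np.argsort(recips, kind="stable")]
        # stable argsort on distinct floats == lexsort tie-break on ids
        assert list(curve.genes) == expected

    def test_log_transform_preserves_order_changes_y(self):
        rt = ratio_table([2.0, 1.0, 0.25, 0.05])
        lin = build_rank_curve(rt, "MC", "linear")
        log = build_rank_curve(rt, "MC", "log")
        assert list(lin.genes) == list(log.genes)
        assert not np.allclose(lin.y, log.y)
        assert log.y[0] == 0.0 and log.y[-1] == 1.0


class TestTangent:
    def test_parabola_tangent_at_half(self):
        x = np.linspace(0, 1, 1001)
        idx, _ = tangent_point(curve_from_xy(x, x**2))
        assert x[idx] == pytest.approx(0.5)

    def test_flat_line_returns_last_point_with_warning(self, caplog):
        x = np.linspace(0, 1, 11)
        with caplog.at_level("WARNING", logger="dehop"):
            idx, _ = tangent_point(curve_from_xy(x, x))
        assert idx == 10
        assert any("flat" in r.message for r in caplog.records)

    def test_random_convex_curves_match_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            n = int(rng.integers(5, 60))
            slopes = np.sort(rng.exponential(1.0, n - 1))  # convex: increasing slopes
            y = np.concatenate([[0.0], np.cumsum(slopes)])
            y = y / y[-1]
            curve = curve_from_xy(np.linspace(0, 1, n), y)
            idx, _ = tangent_point(curve)
            assert idx == brute_force_tangent(curve)

    def test_slope_scan_agrees_on_smooth_convex_curve(self):
        x = np.linspace(0, 1, 2001)
        curve = curve_from_xy(x, x**3)
        i1, _ = tangent_point(curve)
        i2, _ = tangent_point_slope_scan(curve)
        # slope-1 point of y = x^3 is x = 1/sqrt(3)
        assert x[i1] == pytest.approx(3 ** -0.5, abs=2e-3)
        assert abs(i1 - i2) <= 1


@given(st.integers(min_value=0, max_value=10_000))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_tangent_matches_brute_force_on_generated_convex_curves(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 40))
    slopes = np.sort(rng.gamma(0.7, 1.0, n - 1) + 1e-9)
    y = np.concatenate([[0.0], np.cumsum(slopes)])
    y /= y[-1]
    curve = curve_from_xy(np.linspace(0, 1, n), y)
    idx, _ = tangent_point(curve)
    assert idx == brute_force_tangent(curve)


class TestSidePopulation:
    def test_membership_rules(self, small_truth_exact):
        truth = small_truth_exact
        rt = compute_ratios(truth.contaminated, truth.wells, "pool1")
        ref = most_abundant_type(truth.wells)
        side = identify_side_population(rt, truth.markers, ref)
        # deterministic model, pure markers: every non-self marker above
        # the TPM floor has phi_bar exactly r < 1% and joins
        non_self = truth.markers.non_self_genes(ref)
        lib = pd.Series(rt.tpm_lib_avg, index=rt.genes)
        expected = {g for g in non_self if lib[g] >= side.min_lib_tpm}
        assert set(side.genes) == expected
        assert len(side) > 0

    def test_non_specific_marker_excluded(self):
        rt = ratio_table([0.006, 0.05], lib_avgs=[500.0, 500.0])
        markers = _marker_frame(["g0", "g1"], ["DC", "DC"])
        side = identify_side_population(rt, markers, "MC")
        assert list(side.genes) == ["g0"]

    def test_low_expression_marker_excluded(self):
        rt = ratio_table([0.006, 0.006], lib_avgs=[500.0, 2.0])
        markers = _marker_frame(["g0", "g1"], ["DC", "DC"])
        side = identify_side_population(rt, markers, "MC")
        assert list(side.genes) == ["g0"]

    def test_mean_phi_bar_is_the_estimate(self):
        rt = ratio_table([0.004, 0.009], lib_avgs=[500.0, 500.0])
        markers = _marker_frame(["g0", "g1"], ["DC", "DC"])
        side = identify_side_population(rt, markers, "MC")
        est = estimate_rate_side_population(rt, side)
        assert est.rate == pytest.approx(0.0065)
        assert est.method == "side_population_mean"

    def test_single_gene_side_population(self):
        rt = ratio_table([0.004, 0.5], lib_avgs=[500.0, 500.0])
        markers = _marker_frame(["g0"], ["DC"])
        side = identify_side_population(rt, markers, "MC")
        est = estimate_rate_side_population(rt, side)
        assert est.rate == pytest.approx(0.004)

    def test_empty_side_population_error(self):
        rt = ratio_table([0.5], lib_avgs=[500.0])
        markers = _marker_frame(["g0"], ["DC"])
        side = identify_side_population(rt, markers, "MC")
        with pytest.raises(ValidationError, match="empty side population"):
            estimate_rate_side_population(rt, side)

    def test_no_donor_types_error(self):
        rt = ratio_table([0.5])
        markers = _marker_frame(["g0"], ["MC"])
        with pytest.raises(ValidationError, match="donor"):
            identify_side_population(rt, markers, "MC")

    def test_exact_recovery_under_deterministic_model(self, small_truth_exact):
        truth = small_truth_exact
        rt = compute_ratios(truth.contaminated, truth.wells, "pool1")
        ref = most_abundant_type(truth.wells)
        side = identify_side_population(rt, truth.markers, ref)
        est = estimate_rate_side_population(rt, side)
        assert est.rate == pytest.approx(truth.true_rate, rel=1e-9)


def _marker_frame(genes, types):
    from dehop import MarkerTable

    return MarkerTable(pd.DataFrame({"gene": genes, "cell_type": types}))


class TestRankEstimate:
    def test_recovers_rate_within_factor_two(self, small_truth):
        truth = small_truth
        rt = compute_ratios(truth.contaminated, truth.wells, "pool1")
        est = estimate_rate_rank(rt, most_abundant_type(truth.wells))
        assert truth.true_rate / 2 <= est.rate <= truth.true_rate * 2

    def test_invariant_to_gene_order_permutation(self, small_truth):
        truth = small_truth
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(truth.contaminated.genes))
        shuffled = ExpressionMatrix(
            truth.contaminated.genes[perm],
            truth.contaminated.cells,
            truth.contaminated.values[perm],
        )
        ref = most_abundant_type(truth.wells)
        e1 = estimate_rate_rank(
            compute_ratios(truth.contaminated, truth.wells, "pool1"), ref
        )
        e2 = estimate_rate_rank(compute_ratios(shuffled, truth.wells, "pool1"), ref)
        assert e1.rate == e2.rate
        assert e1.tangent_gene == e2.tangent_gene

    def test_partition_separates_self_markers_from_floor(self, small_truth):
        truth = small_truth
        rt = compute_ratios(truth.contaminated, truth.wells, "pool1")
        ref = most_abundant_type(truth.wells)
        est = estimate_rate_rank(rt, ref)
        below = set(est.partition.reference_expressed)
        self_markers = set(truth.markers.genes_for(ref))
        assert len(self_markers & below) / len(self_markers) >= 0.95
        # pure non-self side genes sit deep in the hopping floor: in the
        # top half of the rank curve, near the tangent's phi_bar
        side = identify_side_population(rt, truth.markers, ref)
        curve = est.details["_curve"]
        rank_of = {g: i for i, g in enumerate(curve.genes)}
        pos = np.array([rank_of[g] for g in side.genes]) / len(curve.genes)
        assert np.all(pos > 0.5)

    def test_no_contamination_yields_no_hopping_floor(self):
        truth = simulate(small_config(rate=0.0, reads_per_cell=None))
        rt = compute_ratios(truth.contaminated, truth.wells, "pool1")
        est = estimate_rate_rank(rt, most_abundant_type(truth.wells))
        # without hopping the tangent lands among genuinely expressed
        # genes, far above any plausible hop rate
        assert est.rate > 0.05

    def test_cross_estimator_consistency_within_factor_two(self, small_truth):
        truth = small_truth
        rt = compute_ratios(truth.contaminated, truth.wells, "pool1")
        ref = most_abundant_type(truth.wells)
        rank = estimate_rate_rank(rt, ref)
        side = identify_side_population(rt, truth.markers, ref)
        sp = estimate_rate_side_population(rt, side)
        ratio = max(rank.rate, sp.rate) / min(rank.rate, sp.rate)
        assert ratio < 2.0


class TestEmptyWellEstimator:
    def test_constructed_identity(self):
        rng = np.random.default_rng(9)
        lib = rng.lognormal(3, 1, 50)
        r = 0.004
        cells = np.tile(lib[:, None], (1, 6))
        vals = np.hstack([cells, r * lib[:, None]])
        m = ExpressionMatrix(
            [f"g{i}" for i in range(50)], [f"c{j}" for j in range(7)], vals
        )
        w = wells_of(["MC"] * 6, n_empty=1)
        w = w.subset([f"c{j}" for j in range(6)] + ["e0"])
        m = ExpressionMatrix(m.genes, list(w.cell_ids), vals)
        est = estimate_rate_empty_wells(m, w)
        assert est.rate == pytest.approx(r, rel=1e-12)

    def test_all_zero_empties_give_zero_rate_flagged_correlation(self):
        vals = np.array([[10.0, 20.0, 0.0], [30.0, 40.0, 0.0]])
        w = wells_of(["MC"] * 2, n_empty=1)
        m = ExpressionMatrix(["g1", "g2"], list(w.cell_ids), vals)
        est = estimate_rate_empty_wells(m, w)
        assert est.rate == 0.0
        assert est.details["spearman_empty_vs_library"] is None

    def test_no_empty_wells_error(self, small_truth):
        wells = small_truth.wells
        cells_only = wells.subset(list(wells.ids_with_status("cell")))
        with pytest.raises(ValidationError, match="empty"):
            estimate_rate_empty_wells(small_truth.contaminated, cells_only)


class TestEstimateRates:
    def test_all_methods_per_pool(self, small_truth):
        ests = estimate_rates(
            small_truth.contaminated,
            small_truth.wells,
            small_truth.markers,
            threshold=0.05,
        )
        methods = {e.method for e in ests}
        assert methods == {"rank_tangent", "side_population_mean", "empty_well"}
        assert all(e.pool_id == "pool1" or e.method == "empty_well" for e in ests)

    def test_side_without_markers_rejected(self, small_truth):
        with pytest.raises(ValidationError, match="marker"):
            estimate_rates(
                small_truth.contaminated, small_truth.wells, None, methods=("side",)
            )

    def test_estimate_to_dict_is_json_ready(self, small_truth):
        import json

        ests = estimate_rates(
            small_truth.contaminated,
            small_truth.wells,
            small_truth.markers,
            methods=("rank", "side"),
            threshold=0.05,
        )
        text = json.dumps([e.to_dict() for e in ests])
        assert "rank_tangent" in text
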