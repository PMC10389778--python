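import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tfdep import (
    FilterConfig,
    analyze_dependence,
    build_dependence_points,
    call_dependence,
    fit_line,
    iterative_filter,
    split_sides,
)
from tfdep import test_bias as bias_p  # aliased so pytest does not collect it
from tfdep.dependence import (
    ABOVE,
    BELOW,
    DEPENDENT_ENHANCED,
    DEPENDENT_IMPAIRED,
    F_VS_ZERO,
    INDEPENDENT_CALL,
    InsufficientPointsError,
)


def _points(x, y, prefix="g"):
    return pd.DataFrame({"gene_id": [f"{prefix}{i}" for i in range(len(x))], "x": x, "y": y})


def _records(gene_ids, log2fc, status="up"):
    return pd.DataFrame({
        "gene_id": gene_ids,
        "log2fc": log2fc,
        "p_value": 0.0,
        "adj_p": 0.0,
        "status": status,
    })


class TestBuildPoints:
    def test_identical_fold_changes_give_y_zero(self):
        genes = ["a", "b", "c"]
        r1 = _records(genes, [1.0, 2.0, 3.0])
        r2 = _records(genes, [1.0, 2.0, 3.0])
        pts = build_dependence_points(r1, r2, genes)
        assert (pts["y"] == 0).all()

    def test_zero_bg2_fold_change_gives_y_equal_x(self):
        genes = ["a", "b", "c"]
        r1 = _records(genes, [1.5, 2.5, 3.5])
        r2 = _records(genes, [0.0, 0.0, 0.0])
        pts = build_dependence_points(r1, r2, genes)
        np.testing.assert_array_equal(pts["y"].to_numpy(), pts["x"].to_numpy())

    def test_point_arithmetic(self):
        pts = build_dependence_points(_records(["g"], [3.0]), _records(["g"], [1.0]), ["g"])
        assert (pts.loc[0, "x"], pts.loc[0, "y"]) == (3.0, 2.0)

    def test_missing_genes_dropped_with_count(self):
        r1 = _records(["a", "b"], [1.0, 2.0])
        r2 = _records(["a"], [0.5])
        pts = build_dependence_points(r1, r2, ["a", "b"])
        assert list(pts["gene_id"]) == ["a"]
        assert pts.attrs["n_dropped"] == 1

    def test_empty_subset_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            build_dependence_points(_records(["a"], [1.0]), _records(["a"], [1.0]), [])


class TestSplitSides:
    def test_all_on_line(self):
        above, below, on_line = split_sides(_points([1, 2], [0.0, 0.0]))
        assert len(above) == len(below) == 0
        assert len(on_line) == 2

    def test_sizes(self):
        above, below, on_line = split_sides(_points([1, 2, 3], [1.0, -1.0, 0.0]))
        assert (len(above), len(below), len(on_line)) == (1, 1, 1)

    def test_sign_flip_swaps_sides(self):
        pts = _points([1, 2, 3, 4], [0.5, -0.25, 1.5, 0.0])
        above, below, _ = split_sides(pts)
        flipped = pts.assign(y=-pts["y"])
        above_f, below_f, _ = split_sides(flipped)
        assert list(above["gene_id"]) == list(below_f["gene_id"])
        assert list(below["gene_id"]) == list(above_f["gene_id"])


class TestFitLine:
    def test_collinear_identity(self):
        fit = fit_line([1, 2, 3], [1, 2, 3])
        assert fit.slope == 1.0
        assert fit.intercept == 0.0
        assert fit.r_squared == 1.0
        assert fit.spearman_rho == 1.0

    def test_reversed_monotone_gives_rho_minus_one(self):
        fit = fit_line([1, 2, 3, 4], [10, 7, 3, 1])
        assert fit.spearman_rho == -1.0

    def test_three_point_closed_form(self):
        """Oracle: Sxy=1.5, Sxx=2, Syy=7/6 -> slope 0.75, intercept -1/6, r2=27/28."""
        fit = fit_line([1, 2, 3], [0.5, 1.5, 2.0])
        assert fit.slope == pytest.approx(0.75)
        assert fit.intercept == pytest.approx(-1 / 6)
        assert fit.r_squared == pytest.approx(1.5**2 / (2 * 7 / 6))
        assert fit.r_squared == pytest.approx(0.9643, abs=1e-4)

    def test_matches_scipy_linregress_on_random_cloud(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 40)
        y = 0.7 * x + rng.normal(0, 0.5, 40)
        fit = fit_line(x, y)
        ref = stats.linregress(x, y)
        assert fit.slope == pytest.approx(ref.slope, rel=1e-12)
        assert fit.intercept == pytest.approx(ref.intercept, rel=1e-12)
        assert fit.r_squared == pytest.approx(ref.rvalue**2, rel=1e-9)

    def test_constant_y_gives_zero_slope_and_zero_r2(self):
        fit = fit_line([1, 2, 3], [5.0, 5.0, 5.0])
        assert fit.slope == 0.0
        assert fit.r_squared == 0.0

    @pytest.mark.parametrize("x, y", [([1], [1]), ([2, 2, 2], [1, 2, 3])])
    def test_insufficient_points(self, x, y):
        with pytest.raises(InsufficientPointsError, match="insufficient"):
            fit_line(x, y)


class TestBias:
    def test_all_zero_y_gives_p_one(self):
        assert bias_p([1, 2, 3], [0, 0, 0]) == 1.0
        assert bias_p([1, 2, 3], [0, 0, 0], method=F_VS_ZERO) == 1.0

    def test_exact_diagonal_gives_p_zero(self):
        assert bias_p([1, 2, 3], [1, 2, 3]) == 0.0
        assert bias_p([1, 2, 3], [1, 2, 3], method=F_VS_ZERO) == 0.0

    def test_f_test_matches_hand_computed_tail(self):
        """Oracle: F computed from hand-evaluated SS0 and SS1."""
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 5, 25)
        y = 0.4 * x + rng.normal(0.2, 0.5, 25)
        ref = stats.linregress(x, y)
        ss1 = float(np.sum((y - ref.intercept - ref.slope * x) ** 2))
        ss0 = float(np.sum(y**2))
        f = ((ss0 - ss1) / 2) / (ss1 / (len(x) - 2))
        expected = stats.f.sf(f, 2, len(x) - 2)
        assert bias_p(x, y, method=F_VS_ZERO) == pytest.approx(expected, rel=1e-12)

    def test_slope_test_matches_scipy_linregress(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 5, 30)
        y = 0.1 * x + rng.normal(0, 1.0, 30)
        assert bias_p(x, y) == pytest.approx(stats.linregress(x, y).pvalue, rel=1e-9)

    def test_needs_three_points(self):
        with pytest.raises(InsufficientPointsError):
            bias_p([1, 2], [1, 2])


class TestIterativeFilter:
    def test_collinear_converges_first_iteration_with_all_points(self):
        x = np.arange(1.0, 11.0)
        fit = iterative_filter(_points(x, 2 * x + 1))
        assert fit.converged
        assert fit.n_iterations == 1
        assert fit.n_points == 10
        assert fit.slope == pytest.approx(2.0)
        assert fit.r_squared == 1.0

    def test_single_displaced_point_is_excluded(self):
        """20 collinear points plus one displaced 10 units perpendicular:
        the filter must drop exactly the displaced point and recover the line."""
        x20 = np.arange(1.0, 21.0)
        y20 = 2 * x20 + 1
        xs = np.append(x20, 10.0)
        ys = np.append(y20, 21.0 + 10 * np.sqrt(5))  # vertical 10*sqrt(5) = perpendicular 10
        fit = iterative_filter(_points(xs, ys))
        assert fit.converged
        assert fit.n_points == 20
        assert "g20" not in fit.included_gene_ids
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)

    def test_too_few_points_is_a_non_converged_fit(self):
        fit = iterative_filter(_points([1.0, 2.0], [1.0, 2.0]))
        assert not fit.converged
        assert fit.included_gene_ids == []
        assert fit.bias_p == 1.0

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        pts = _points(rng.uniform(1, 4, 100), rng.normal(1, 0.5, 100))
        f1 = iterative_filter(pts)
        f2 = iterative_filter(pts)
        assert f1 == f2

    def test_terminates_within_max_iterations_on_random_clouds(self):
        config = FilterConfig()
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(5, 60))
            pts = _points(rng.uniform(0, 5, n), rng.normal(0, 1, n))
            fit = iterative_filter(pts, config)
            assert fit.n_iterations <= config.max_iterations

    def test_scale_coherence(self):
        """Multiplying x and y by a common factor leaves r2, rho and the
        inclusion set unchanged (distances and threshold scale together)."""
        rng = np.random.default_rng(6)
        x = rng.uniform(1, 4, 80)
        y = x + rng.normal(0, 0.4, 80)
        base = iterative_filter(_points(x, y))
        scaled = iterative_filter(_points(10 * x, 10 * y))
        assert scaled.included_gene_ids == base.included_gene_ids
        assert scaled.r_squared == pytest.approx(base.r_squared, rel=1e-9)
        assert scaled.spearman_rho == pytest.approx(base.spearman_rho, rel=1e-12)

    def test_filter_config_validation(self):
        with pytest.raises(ValueError):
            FilterConfig(distance_multiplier=0)
        with pytest.raises(ValueError):
            FilterConfig(bias_test="bogus")


class TestCallDependence:
    def test_all_on_line_is_all_independent(self):
        pts = _points([1, 2, 3, 4], [0.0, 0.0, 0.0, 0.0])
        above, below, _ = split_sides(pts)
        fa = iterative_filter(above, side=ABOVE)
        fb = iterative_filter(below, side=BELOW)
        calls = call_dependence(pts, fa, fb)
        assert (calls["call"] == INDEPENDENT_CALL).all()

    def test_perfect_dependence_calls_every_gene_impaired(self):
        x = np.linspace(1, 4, 30)
        pts = _points(x, x)
        above, below, _ = split_sides(pts)
        fa = iterative_filter(above, side=ABOVE)
        fb = iterative_filter(below, side=BELOW)
        calls = call_dependence(pts, fa, fb)
        assert (calls["call"] == DEPENDENT_IMPAIRED).all()

    def test_noise_cloud_false_positive_rate_is_near_alpha(self):
        """Monte Carlo over 200 seeded replicates of pure technical noise:
        the per-side rejection rate should track alpha_bias (mild inflation
        from the distance filter is tolerated up to 2.5x)."""
        config = FilterConfig()
        rejections = 0
        n_sides = 0
        for seed in range(200):
            rng = np.random.default_rng(10_000 + seed)
            pts = _points(rng.uniform(1, 4, 200), rng.normal(0, 0.3, 200))
            above, below, _ = split_sides(pts)
            for side_pts, side in ((above, ABOVE), (below, BELOW)):
                fit = iterative_filter(side_pts, config, side=side)
                n_sides += 1
                if fit.converged and fit.bias_p < config.alpha_bias:
                    rejections += 1
        rate = rejections / n_sides
        assert rate <= 2.5 * config.alpha_bias
        assert rate >= 0.0


class TestAnalyzeDependence:
    def test_enhanced_side_symmetry(self):
        genes = [f"g{i}" for i in range(40)]
        fc1 = np.linspace(1.2, 4, 40)
        r1 = _records(genes, fc1)
        r2 = _records(genes, fc1 * 2)  # induction doubled in background 2 -> y < 0
        result = analyze_dependence(r1, r2)
        assert result.fit_above.n_points == 0
        assert (result.points["call"] == DEPENDENT_ENHANCED).all()

    def test_recovers_impaired_genes_with_noise(self, recovery_data):
        _, truth, de_wt, de_ko = recovery_data
        result = analyze_dependence(de_wt, de_ko)
        pts = result.points.set_index("gene_id")
        called = set(pts.index[pts["call"] == DEPENDENT_IMPAIRED])
        truth_impaired = set(truth.index[truth["dependence_class"] == "impaired"])
        analyzed_impaired = truth_impaired & set(pts.index)
        sensitivity = len(called & truth_impaired) / len(analyzed_impaired)
        precision = len(called & truth_impaired) / len(called)
        assert sensitivity >= 0.9
        assert precision >= 0.9
        assert result.fit_above.slope == pytest.approx(1.0, abs=0.1)

    def test_subset_must_exist(self):
        r = _records(["a"], [2.0], status="ns")
        with pytest.raises(ValueError, match="status"):
            analyze_dependence(r, r, subset="up")
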