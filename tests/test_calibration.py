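import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from albupred import (
    bin_summaries,
    fit_linear_spline,
    fit_restricted_cubic_spline,
    invert_median_uacr,
    load_published_model,
    predict_median_uacr,
    select_knot_count,
    slope_change_tests,
    standard_knots,
)
from albupred.calibration import (
    SplineModel,
    SplineSegment,
    restricted_cubic_basis,
)


class TestBinSummaries:
    def test_three_point_quartiles(self):
        # interpolated quartiles of {10, 20, 30}
        (b,) = bin_summaries([(0.05, 10), (0.05, 20), (0.05, 30)])
        assert (b.q1, b.median_uacr, b.q3) == (15, 20, 25)
        assert b.n == 3

    def test_single_value(self):
        (b,) = bin_summaries([(0.03, 30)])
        assert (b.q1, b.median_uacr, b.q3) == (30, 30, 30)

    def test_membership_by_nearest_multiple(self):
        bins = bin_summaries([(0.044, 1), (0.046, 2), (0.054, 3)])
        assert [b.bin_label for b in bins] == [0.04, 0.05]
        assert [b.n for b in bins] == [1, 2]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bin_summaries([])

    def test_counts_conserved(self):
        rng = np.random.default_rng(3)
        pairs = list(zip(rng.uniform(0, 0.3, 200), rng.uniform(1, 100, 200)))
        assert sum(b.n for b in bin_summaries(pairs)) == 200


class TestStandardKnots:
    def test_percentile_oracle(self):
        values = np.arange(1.0, 101.0)
        expected = np.percentile(values, [10, 50, 90], method="linear")
        assert standard_knots(values, 3) == pytest.approx(expected)

    def test_four_knot_locations(self):
        values = np.arange(0.0, 1001.0)
        assert standard_knots(values, 4) == pytest.approx([50, 350, 650, 950])

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError, match="fewer knots"):
            standard_knots(np.ones(50), 4)

    def test_unsupported_count_rejected(self):
        with pytest.raises(ValueError):
            standard_knots(np.arange(100.0), 6)


def _normal_equation_oracle(x, y, ln_knots):
    """Independent OLS solution on the explicit piecewise-linear basis."""
    cols = [np.ones_like(x), np.minimum(x, ln_knots[0])]
    for j in range(1, len(ln_knots)):
        cols.append(np.clip(x - ln_knots[j - 1], 0,
                            ln_knots[j] - ln_knots[j - 1]))
    cols.append(np.maximum(x - ln_knots[-1], 0))
    X = np.column_stack(cols)
    return np.linalg.solve(X.T @ X, X.T @ y), X


class TestLinearSpline:
    def test_exact_broken_line_recovered(self):
        # points on a 2-segment line joined at ln(50): slopes 0.5 then 1.5
        knot = 50.0
        x = np.log(np.array([5, 10, 20, 40, 50, 80, 120, 300.0]))
        k = np.log(knot)
        y = np.where(x <= k, 1.0 + 0.5 * x, 1.0 + 0.5 * k + 1.5 * (x - k))
        model = fit_linear_spline(x, y, [knot])
        assert model.segments[0].slope == pytest.approx(0.5, abs=1e-9)
        assert model.segments[1].slope == pytest.approx(1.5, abs=1e-9)
        assert model.rss == pytest.approx(0, abs=1e-18)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(1, 6, 40)
        y = 0.5 + 0.8 * x + rng.normal(0, 0.3, 40)
        knots = [np.exp(3.0)]
        model = fit_linear_spline(x, y, knots)
        beta, _ = _normal_equation_oracle(x, y, np.log(knots))
        assert model.basis_coefficients == pytest.approx(beta, rel=1e-8)

    @given(seed=st.integers(0, 1000))
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_continuity_at_every_knot(self, seed):
        rng = np.random.default_rng(seed)
        x = np.sort(rng.uniform(0.5, 7, 60))
        y = np.sin(x) + rng.normal(0, 0.2, 60)
        knots = np.exp(np.percentile(x, [20, 50, 80]))
        model = fit_linear_spline(x, y, knots)
        for left, right in zip(model.segments, model.segments[1:]):
            k = np.log(left.hi)
            assert left.intercept + left.slope * k == pytest.approx(
                right.intercept + right.slope * k, abs=1e-9)

    def test_empty_segment_reported(self):
        # no observations between the knots at 50 and 100
        x = np.log(np.array([5, 10, 15, 200, 300.0]))
        with pytest.raises(ValueError, match="segment"):
            fit_linear_spline(x, x, [50.0, 100.0])

    def test_aic_definition(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(1, 6, 30)
        y = x + rng.normal(0, 0.2, 30)
        model = fit_linear_spline(x, y, [np.exp(3.5)])
        expected = 30 * np.log(model.rss / 30) + 2 * (model.p + 1)
        assert model.aic == pytest.approx(expected)


class TestRestrictedCubicSpline:
    def test_linearity_is_nested(self):
        x = np.linspace(1, 6, 50)
        y = 0.7 * x + 0.2
        knots = np.exp([2.0, 3.5, 5.0])
        model = fit_restricted_cubic_spline(x, y, knots)
        assert model.basis_coefficients[2:] == pytest.approx(0, abs=1e-8)
        assert model.predict_ln(x) == pytest.approx(y, abs=1e-8)

    def test_basis_truncated_power_formula(self):
        t = np.array([1.0, 2.5, 4.0])
        x = np.array([0.5, 1.0, 2.5, 4.0, 5.0])
        basis = restricted_cubic_basis(x, t)

        def plus3(v):
            return np.maximum(v, 0.0) ** 3

        expected = (plus3(x - t[0])
                    - plus3(x - t[1]) * (t[2] - t[0]) / (t[2] - t[1])
                    + plus3(x - t[2]) * (t[1] - t[0]) / (t[2] - t[1]))
        assert basis[:, 1] == pytest.approx(expected)
        # linear beyond the boundary knots: second derivative vanishes
        xs = np.array([4.5, 5.0, 5.5])
        col = restricted_cubic_basis(xs, t)[:, 1]
        assert col[2] - 2 * col[1] + col[0] == pytest.approx(0, abs=1e-9)

    def test_too_few_knots_rejected(self):
        with pytest.raises(ValueError):
            fit_restricted_cubic_spline([1, 2, 3], [1, 2, 3], [1.0, 2.0])

    def test_aic_shares_convention_with_linear(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(1, 6, 60)
        y = x + rng.normal(0, 0.1, 60)
        knots = np.exp([2.0, 3.5, 5.0])
        lin = fit_linear_spline(x, y, knots)
        rcs = fit_restricted_cubic_spline(x, y, knots)
        for m in (lin, rcs):
            assert m.aic == pytest.approx(
                m.n * np.log(m.rss / m.n) + 2 * (m.p + 1))


class TestKnotSelection:
    def test_straight_line_prefers_fewest_knots(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(1, 7, 400)
        y = 0.9 * x + 0.5 + rng.normal(0, 0.25, 400)
        best, aic_table, _ = select_knot_count(x, y, "linear")
        assert best == 3
        # no candidate buys a meaningful fit improvement over k=3
        assert max(aic_table.values()) - min(aic_table.values()) < 8

    def test_tie_goes_to_smaller_k(self, monkeypatch):
        import albupred.calibration as cal

        def fake_fitter(x, y, knots):
            return SplineModel(kind="linear", knots=np.asarray(knots),
                               aic=1.234567)

        monkeypatch.setitem(cal._FITTERS, "linear", fake_fitter)
        best, _, _ = select_knot_count(np.arange(1.0, 9), np.arange(1.0, 9),
                                       "linear")
        assert best == 3


class TestSlopeChanges:
    def _noisy_model(self, seed=21):
        rng = np.random.default_rng(seed)
        x = np.sort(rng.uniform(1, 7, 50))
        k = 3.5
        y = np.where(x <= k, 0.5 * x, 0.5 * k + 1.4 * (x - k))
        y = y + rng.normal(0, 0.15, 50)
        return fit_linear_spline(x, y, [np.exp(k)]), x, y, k

    def test_contrast_vector_oracle(self):
        """t statistic equals the from-scratch c'beta / sqrt(c'Vc) contrast."""
        model, x, y, k = self._noisy_model()
        beta, X = _normal_equation_oracle(x, y, [k])
        resid = y - X @ beta
        sigma2 = resid @ resid / (len(y) - X.shape[1])
        V = sigma2 * np.linalg.inv(X.T @ X)
        c = np.array([0.0, -1.0, 1.0])
        t_oracle = (c @ beta) / np.sqrt(c @ V @ c)
        (change,) = slope_change_tests(model)
        assert change.t == pytest.approx(t_oracle, rel=1e-8)
        assert change.difference == pytest.approx(c @ beta, rel=1e-8)

    def test_equal_slopes_give_null_result(self):
        x = np.linspace(1, 7, 40)
        model = fit_linear_spline(x, 2.0 + 0.8 * x, [np.exp(4.0)])
        (change,) = slope_change_tests(model)
        assert change.difference == pytest.approx(0, abs=1e-7)
        assert change.p == pytest.approx(1, abs=1e-5)

    def test_published_model_lacks_covariance(self, all_model):
        with pytest.raises(ValueError, match="covariance"):
            slope_change_tests(all_model)


class TestPredictInvert:
    def test_identity_model(self):
        ident = SplineModel(kind="linear", knots=np.array([100.0]),
                            segments=[SplineSegment(0, 100, 0.0, 1.0),
                                      SplineSegment(100, np.inf, 0.0, 1.0)],
                            domain=(1.0, 1000.0))
        for v in (3.0, 100.0, 500.0):
            assert predict_median_uacr(ident, v) == pytest.approx(v)
            assert invert_median_uacr(ident, v) == pytest.approx(v)

    def test_out_of_domain_rejected(self, all_model):
        with pytest.raises(ValueError, match="domain"):
            predict_median_uacr(all_model, 800.0)
        with pytest.raises(ValueError):
            predict_median_uacr(all_model, 0.0)

    def test_round_trip(self, all_model):
        for upcr in (5, 19.9, 20, 59, 77, 150, 349, 420, 500):
            target = predict_median_uacr(all_model, upcr)
            assert invert_median_uacr(all_model, target) == pytest.approx(
                upcr, rel=1e-9)

    def test_non_monotone_model_rejected(self):
        bad = SplineModel(kind="linear", knots=np.array([100.0]),
                          segments=[SplineSegment(0, 100, 0.0, 1.0),
                                    SplineSegment(100, np.inf, 9.2, -1.0)],
                          domain=(1.0, 1000.0))
        with pytest.raises(ValueError, match="monotone"):
            invert_median_uacr(bad, 30.0)

    def test_target_out_of_range_rejected(self, all_model):
        with pytest.raises(ValueError, match="range"):
            invert_median_uacr(all_model, 5000.0)

    def test_unknown_population_rejected(self):
        with pytest.raises(KeyError):
            load_published_model("weaver")
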