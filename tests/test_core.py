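import math
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenocpt import (
    PivotConfig,
    TimeSeries,
    build_basis,
    enumerate_configs,
    least_squares_fit,
    log_evidence,
    sample_configs_mc,
)
from phenocpt.core import _basis_stack, fit_model_class, n_configurations


def _series(n, seed=0, sd=2.0, slope=-0.5, gaps=()):
    rng = np.random.default_rng(seed)
    years = np.array([y for y in range(1901, 1901 + n + len(gaps)) if y not in gaps])[:n]
    vals = 50.0 + slope * (years - years[0]) + rng.normal(0, sd, n)
    return TimeSeries(years, vals, "temperature", f"n{n}")


class TestEnumeration:
    def test_one_changepoint_count_is_n_minus_2(self):
        s = _series(110)
        assert len(enumerate_configs(1, s)) == 108

    def test_zero_changepoints_single_empty_config(self):
        s = _series(10)
        cfgs = enumerate_configs(0, s)
        assert len(cfgs) == 1 and cfgs[0].cpt_years == ()

    def test_two_changepoints_matches_binomial(self):
        s = _series(10)
        cfgs = enumerate_configs(2, s)
        assert len(cfgs) == 28 == math.comb(8, 2)
        # all pairs distinct, ordered, strictly interior
        seen = {c.cpt_years for c in cfgs}
        assert len(seen) == 28
        interior = set(int(y) for y in s.years[1:-1])
        for a, b in seen:
            assert a < b and {a, b} <= interior

    def test_too_many_changepoints_rejected(self):
        s = _series(5)
        with pytest.raises(ValueError):
            enumerate_configs(3, s)

    @given(n=st.integers(5, 16), k=st.integers(0, 3))
    @settings(max_examples=30, deadline=None)
    def test_count_equals_binomial_coefficient(self, n, k):
        if k > n - 3:
            return
        s = _series(n, seed=n)
        assert len(enumerate_configs(k, s)) == math.comb(n - 2, k)


class TestBasis:
    def test_rows_sum_to_one(self):
        s = _series(12)
        for cfg in enumerate_configs(2, s)[:10]:
            A = build_basis(cfg, s)
            np.testing.assert_allclose(A.sum(axis=1), 1.0, atol=1e-12)

    def test_pivot_row_is_unit_vector(self):
        s = _series(12)
        cfg = enumerate_configs(1, s)[4]
        A = build_basis(cfg, s)
        i = int(np.where(s.years == cfg.cpt_years[0])[0][0])
        expected = np.zeros(3)
        expected[1] = 1.0
        np.testing.assert_allclose(A[i], expected, atol=1e-12)

    def test_linear_basis_spans_straight_lines(self):
        s = _series(15, gaps=(1904, 1910))
        A = build_basis(PivotConfig.linear(), s)
        x = s.years.astype(float)
        line = 3.0 + 0.25 * x
        coef = np.array([3.0 + 0.25 * x[0], 3.0 + 0.25 * x[-1]])
        np.testing.assert_allclose(A @ coef, line, atol=1e-9)

    def test_constant_basis_single_ones_column(self):
        s = _series(8)
        A = build_basis(PivotConfig.constant(), s)
        assert A.shape == (8, 1)
        np.testing.assert_array_equal(A, 1.0)

    @given(seed=st.integers(0, 50))
    @settings(max_examples=25, deadline=None)
    def test_partition_of_unity_random_configs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 20))
        s = _series(n, seed=seed)
        k = int(rng.integers(1, min(3, n - 3) + 1))
        cfgs = enumerate_configs(k, s)
        cfg = cfgs[int(rng.integers(len(cfgs)))]
        A = build_basis(cfg, s)
        np.testing.assert_allclose(A.sum(axis=1), 1.0, atol=1e-12)


class TestLeastSquares:
    def test_exact_line_zero_rss(self):
        years = np.arange(1901, 1911)
        vals = 40.0 - 0.5 * (years - 1901)
        s = TimeSeries(years, vals, "temperature")
        fit = least_squares_fit(PivotConfig.linear(), s)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)
        np.testing.assert_allclose(fit.coefficients, [40.0, 35.5], atol=1e-9)

    def test_constant_fit_is_sample_mean(self):
        s = _series(20, seed=3)
        fit = least_squares_fit(PivotConfig.constant(), s)
        assert fit.coefficients[0] == pytest.approx(s.values.mean())
        ss_tot = ((s.values - s.values.mean()) ** 2).sum()
        assert fit.rss == pytest.approx(ss_tot)

    def test_matches_dense_grid_search(self):
        """6-point toy, one change point: brute-force vertex grid search."""
        rng = np.random.default_rng(7)
        years = np.arange(1901, 1907)
        vals = 50 - np.array([0.0, 0.0, 0.0, 2.0, 4.0, 6.0]) + rng.normal(0, 1, 6)
        s = TimeSeries(years, vals, "temperature")
        cfg = PivotConfig(1, (1903,))
        fit = least_squares_fit(cfg, s)

        pivots = np.array([1901.0, 1903.0, 1906.0])

        def rss_of(f):
            return ((vals - np.interp(years, pivots, f)) ** 2).sum()

        # coarse-to-fine grid minimization, independent of linear algebra
        center = np.interp(pivots, years, vals)
        width = 6.0
        best = None
        for _ in range(12):
            axes = [np.linspace(c - width, c + width, 13) for c in center]
            grids = np.array(list(product(*axes)))
            rss_all = [rss_of(f) for f in grids]
            best = grids[int(np.argmin(rss_all))]
            center, width = best, width / 3.0
        np.testing.assert_allclose(fit.coefficients, best, atol=1e-5)
        assert fit.rss == pytest.approx(rss_of(best), abs=1e-8)

    def test_min_rss_nonincreasing_in_ncpt(self):
        s = _series(14, seed=9)
        prev = least_squares_fit(PivotConfig.linear(), s).rss
        for k in (1, 2, 3):
            best = min(least_squares_fit(c, s).rss for c in enumerate_configs(k, s))
            assert best <= prev + 1e-10
            prev = best


class TestLogEvidence:
    def test_translation_leaves_differences_unchanged(self):
        s = _series(12, seed=4)
        s2 = TimeSeries(s.years, s.values + 17.5, "temperature")
        cfgs = [PivotConfig.linear()] + enumerate_configs(1, s)[:5]
        le1 = [log_evidence(least_squares_fit(c, s), s) for c in cfgs]
        le2 = [log_evidence(least_squares_fit(c, s2), s2) for c in cfgs]
        diffs1 = np.diff(le1)
        diffs2 = np.diff(le2)
        np.testing.assert_allclose(diffs1, diffs2, atol=1e-8)

    def test_scaling_shifts_by_minus_n_log_s(self):
        s = _series(12, seed=4)
        scale = 3.7
        s2 = TimeSeries(s.years, s.values * scale, "temperature")
        for c in [PivotConfig.constant(), PivotConfig.linear(), PivotConfig(1, (1906,))]:
            le1 = log_evidence(least_squares_fit(c, s), s)
            le2 = log_evidence(least_squares_fit(c, s2), s2)
            assert le2 - le1 == pytest.approx(-len(s) * math.log(scale), abs=1e-8)

    def test_exact_fit_is_hard_error(self):
        years = np.arange(1901, 1911)
        s = TimeSeries(years, 40.0 - 0.5 * (years - 1901), "temperature")
        fit = least_squares_fit(PivotConfig.linear(), s)
        with pytest.raises(ValueError, match="degenerate exact fit"):
            log_evidence(fit, s)


class TestMonteCarlo:
    def test_same_seed_identical_sample(self):
        s = _series(30, seed=2)
        a = sample_configs_mc(2, s, 500, seed=77)
        b = sample_configs_mc(2, s, 500, seed=77)
        assert a.configs == b.configs
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_weights_normalized(self):
        s = _series(30, seed=2)
        mc = sample_configs_mc(1, s, 300, seed=5)
        assert mc.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_weighted_mean_fit_matches_enumeration(self):
        """Large-n_mc estimate of the averaged 1-cpt polygon vs exact sum."""
        s = _series(30, seed=12, sd=3.0)
        t = s.years.astype(float)
        exact = fit_model_class(s, "1cpt")
        w = np.exp(exact.log_w)
        vals = np.einsum(
            "ctm,cm->ct", _basis_stack(exact.pivots, t), exact.coef
        )
        mean_exact = w @ vals

        mc = fit_model_class(s, "1cpt", n_mc=20_000, force_mode="mc",
                             rng=np.random.default_rng(31))
        wm = np.exp(mc.log_w)
        vals_mc = np.einsum("ctm,cm->ct", _basis_stack(mc.pivots, t), mc.coef)
        mean_mc = wm @ vals_mc
        # every config appears at n_mc >> 28 configs; agreement within 1%
        scale = np.abs(mean_exact).mean()
        assert np.max(np.abs(mean_mc - mean_exact)) < 0.01 * scale


class TestConfigValidation:
    def test_changepoint_must_be_observed_interior_year(self):
        s = _series(10, gaps=(1905,))
        with pytest.raises(ValueError, match="interior observed year"):
            build_basis(PivotConfig(1, (1905,)), s)

    def test_n_configurations_formula(self):
        assert n_configurations(2, 112) == math.comb(110, 2)
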