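import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dendrostress import (
    SplineFit,
    TreeSeries,
    biweight_mean,
    build_gic,
    chronology_stats,
    detrend_tree,
    eps_from_rbar,
    fit_spline,
    growth_indices,
)
from dendrostress.detrend import GrowthIndexSeries, spline_smoothing_parameter


def spline_gain(period: float, carrier_cycles: int = 10) -> float:
    """Frequency-response oracle: fit a sinusoid of wavelength ``period``
    on a series long relative to the wavelength and project the interior
    of the fit back onto the sinusoid."""
    n = int(carrier_cycles * period)
    t = np.arange(n, dtype=float)
    x = np.sin(2 * np.pi * t / period)
    fit = fit_spline(10.0 + x, period=period).fitted - 10.0
    lo, hi = int(2 * period), n - int(2 * period)
    return float(np.dot(fit[lo:hi], x[lo:hi]) / np.dot(x[lo:hi], x[lo:hi]))


class TestFitSpline:
    @pytest.mark.parametrize("n", [50, 100, 200])
    def test_gain_half_at_cutoff_wavelength(self, n):
        assert spline_gain(0.67 * n) == pytest.approx(0.5, abs=0.05)

    def test_high_frequency_passes_into_index(self):
        # a 4-year oscillation should survive detrending almost untouched
        n = 100
        t = np.arange(n, dtype=float)
        x = np.sin(2 * np.pi * t / 4.0)
        fit = fit_spline(10.0 + x, cutoff_fraction=0.67).fitted - 10.0
        gain = np.dot(fit, x) / np.dot(x, x)
        assert abs(gain) < 0.05

    def test_constant_series_reproduced(self):
        fit = fit_spline(np.full(40, 3.7))
        assert np.allclose(fit.fitted, 3.7)

    def test_errors(self):
        with pytest.raises(ValueError, match="too short"):
            fit_spline(np.ones(5))
        with pytest.raises(ValueError, match="non-finite"):
            fit_spline(np.r_[np.ones(20), np.nan])

    def test_smoothing_parameter_monotone_in_period(self):
        assert spline_smoothing_parameter(100.0) > spline_smoothing_parameter(10.0)


def make_tree(widths, first_year=1990, tree_id="T1"):
    years = np.arange(first_year, first_year + len(widths))
    return TreeSeries(tree_id=tree_id, species="SP",
                      widths=pd.Series(np.asarray(widths, float), index=years))


class TestGrowthIndices:
    def test_ratio_identity_and_scaling(self):
        tree = make_tree(np.linspace(2, 4, 20))
        fit = SplineFit(values=tree.widths.to_numpy(),
                        fitted=tree.widths.to_numpy().copy(),
                        cutoff_fraction=0.67, amplitude=0.5, lam=1.0)
        assert np.allclose(growth_indices(tree, fit).indices, 1.0)
        fit.fitted = tree.widths.to_numpy() / 2.0
        assert np.allclose(growth_indices(tree, fit).indices, 2.0)

    def test_elementwise_division(self):
        tree = make_tree([1.0, 2.0])
        fit = SplineFit(values=tree.widths.to_numpy(), fitted=np.array([2.0, 2.0]),
                        cutoff_fraction=0.67, amplitude=0.5, lam=1.0)
        assert np.allclose(growth_indices(tree, fit).indices, [0.5, 1.0])

    def test_nonpositive_fitted_aborts_with_year(self):
        tree = make_tree([1.0, 2.0, 3.0], first_year=2001)
        fit = SplineFit(values=tree.widths.to_numpy(), fitted=np.array([1.0, -0.1, 1.0]),
                        cutoff_fraction=0.67, amplitude=0.5, lam=1.0)
        with pytest.raises(ValueError, match="2002"):
            growth_indices(tree, fit)

    def test_index_mean_near_one_for_positive_series(self):
        rng = np.random.default_rng(5)
        widths = 3.0 * np.exp(-np.arange(50) / 30.0) + 1.0
        widths = widths * rng.lognormal(0.0, 0.15, 50)
        idx = detrend_tree(make_tree(widths)).indices
        assert 0.9 <= idx.mean() <= 1.1


class TestBiweightMean:
    @pytest.mark.parametrize("values,expected", [
        ([1.0, 1.0, 1.0], 1.0),
        ([0.9, 1.0, 1.1], 1.0),
        ([0.8, 1.2], 1.0),  # two points reduce to the arithmetic mean
    ])
    def test_symmetric_sets(self, values, expected):
        assert biweight_mean(values) == pytest.approx(expected)

    def test_outlier_gets_zero_weight(self):
        # |5.0 - median| = 3.95 > 9 * MAD = 1.35, so the outlier drops out
        values = [0.8, 0.9, 1.0, 1.1, 1.2, 5.0]
        assert biweight_mean(values) == pytest.approx(1.0, abs=0.01)

    @given(st.lists(st.floats(0.1, 10.0), min_size=1, max_size=30))
    @settings(deadline=None)
    def test_bounded_by_extremes(self, values):
        m = biweight_mean(values)
        assert min(values) - 1e-9 <= m <= max(values) + 1e-9

    def test_degenerate_spread_falls_back_to_median(self):
        assert biweight_mean([1.0, 1.0, 1.0, 9.0]) == pytest.approx(1.0)


class TestChronologyStats:
    def test_identical_series(self):
        rng = np.random.default_rng(0)
        base = pd.Series(rng.lognormal(0, 0.2, 30), index=np.arange(1990, 2020))
        series = [GrowthIndexSeries(tree_id=f"T{i}", indices=base.copy()) for i in range(4)]
        rbar, eps = chronology_stats(series)
        assert rbar == pytest.approx(1.0)
        assert eps == pytest.approx(1.0)

    def test_eps_formula_spot_check(self):
        # rbar 0.48 with 17 trees: 8.16 / 8.68
        assert eps_from_rbar(0.48, 17) == pytest.approx(0.940, abs=0.001)
        assert eps_from_rbar(0.0, 17) == pytest.approx(0.0)

    @pytest.mark.parametrize("rbar", [0.1, 0.3, 0.5, 0.7])
    def test_eps_monotone_in_rbar_and_n(self, rbar):
        assert eps_from_rbar(rbar + 0.1, 10) > eps_from_rbar(rbar, 10)
        assert eps_from_rbar(rbar, 20) > eps_from_rbar(rbar, 10)

    def test_insufficient_overlap_raises(self):
        a = GrowthIndexSeries("T1", pd.Series([1.0] * 5, index=range(1990, 1995)))
        b = GrowthIndexSeries("T2", pd.Series([1.0] * 5, index=range(2000, 2005)))
        with pytest.raises(ValueError, match="overlap"):
            chronology_stats([a, b])


class TestBuildGic:
    def test_identical_trees(self):
        rng = np.random.default_rng(1)
        widths = (3.0 * np.exp(-np.arange(40) / 20.0) + 1.0) * rng.lognormal(0, 0.1, 40)
        trees = [make_tree(widths, tree_id=f"T{i}") for i in range(3)]
        gic = build_gic(trees)
        assert gic.rbar == pytest.approx(1.0)
        assert gic.eps == pytest.approx(1.0)
        single = detrend_tree(trees[0]).indices
        assert np.allclose(gic.values.to_numpy(), single.to_numpy())

    def test_common_signal_gives_high_eps(self, cedar_forest):
        # 20 trees sharing half their index variance: EPS must clear 0.85
        from dendrostress import build_trees
        cores, _ = cedar_forest
        gic = build_gic(build_trees(cores)["CED"])
        assert gic.eps > 0.85
        assert 0.9 <= gic.values.mean() <= 1.1
        assert (gic.depth == 20).all()
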