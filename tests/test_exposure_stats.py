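"""Descriptive layer: summaries, correlations, ratios, projection, shape."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from indoair import exposure_stats as es
from helpers import make_series


class TestSummarize:
    def test_constant_series_degenerates_cleanly(self):
        s = es.summarize(make_series([5, 5, 5, 5]), bin_count=3)
        assert s.mean == 5 and s.sd == 0 and s.outliers == ()
        assert s.min == s.q1 == s.median == s.q3 == s.max == 5

    def test_tukey_outlier_flagged_with_type7_quartiles(self):
        # hand computation: sorted [1,2,3,4,100], Q1=2, Q3=4 (linear
        # interpolation), IQR=2, fences [-1, 7] -> only 100 outside
        s = es.summarize(make_series([1, 2, 3, 4, 100]))
        assert s.q1 == 2 and s.median == 3 and s.q3 == 4
        assert s.outliers == (100.0,)

    def test_modal_bin_is_most_populated(self):
        x = [0, 1, 1.1, 1.2, 9, 10]
        s = es.summarize(make_series(x), bin_count=10)
        lo, hi = s.modal_bin
        assert lo <= 1 and hi >= 1.2
        assert s.modal_freq == pytest.approx(3 / 6)

    def test_quartile_ordering_invariant(self):
        rng = np.random.default_rng(0)
        s = es.summarize(make_series(rng.lognormal(3, 1, 200)))
        assert s.min <= s.q1 <= s.median <= s.q3 <= s.max

    def test_errors(self):
        with pytest.raises(ValueError, match="no data"):
            es.summarize(make_series([]))
        with pytest.raises(ValueError):
            es.summarize(make_series([1, 2]), bin_count=0)

    def test_synthetic_pm10_mean_matches_campaign_calibration(self, default_campaign):
        series, _ = default_campaign
        s = es.summarize(series["indoor:PM10"])
        se = s.sd / np.sqrt(s.n)
        assert abs(s.mean - 131.29) < 2 * se

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        a=st.floats(0.1, 10),
        b=st.floats(-50, 50),
        seed=st.integers(0, 100),
    )
    def test_affine_equivariance(self, a, b, seed):
        x = np.random.default_rng(seed).normal(10, 3, 50)
        s0 = es.summarize(make_series(np.abs(x)))
        x1 = a * np.abs(x) + abs(b)
        s1 = es.summarize(make_series(x1))
        assert s1.mean == pytest.approx(a * s0.mean + abs(b), rel=1e-9)
        assert s1.median == pytest.approx(a * s0.median + abs(b), rel=1e-9)
        assert s1.sd == pytest.approx(a * s0.sd, rel=1e-9)


class TestPearson:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3], [1, 2, 3], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 2, 3], [1, 2, 4], 0.9819805060619655),
        ],
    )
    def test_product_moment_values(self, x, y, expected):
        assert es.pearson(x, y).r == pytest.approx(expected, abs=1e-12)

    def test_one_tail_halves_two_tail_p(self):
        x, y = [1, 2, 3, 4, 6], [1, 2, 2, 5, 5]
        two = es.pearson(x, y, tail="two")
        one = es.pearson(x, y, tail="one")
        assert one.p_value == pytest.approx(two.p_value / 2)

    def test_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            es.pearson([1, 2, 3], [1, 2])
        with pytest.raises(es.DegenerateInputError):
            es.pearson([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            es.pearson([1, 2], [1, 2])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5), seed=st.integers(0, 50))
    def test_affine_invariance_with_sign_flip(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=30), rng.normal(size=30)
        r0 = es.pearson(x, y).r
        assert es.pearson(a * x + b, y).r == pytest.approx(r0, abs=1e-9)
        assert es.pearson(-a * x + b, y).r == pytest.approx(-r0, abs=1e-9)


class TestSizeResolvedCorrelation:
    def test_bc_duplicated_into_bin_gives_unit_correlation(self, default_campaign):
        _, spectrum = default_campaign
        rng = np.random.default_rng(0)
        n = 50
        ts = pd.date_range("2022-09-26 09:00", periods=n, freq="min")
        bc_vals = rng.lognormal(1, 0.3, n)
        mass = rng.lognormal(0, 0.3, (n, 31))
        mass[:, 0] = bc_vals  # channel 0 is an exact copy of the BC series
        spec = es.SizeSpectrumSeries(ts, spectrum.bins, mass)
        bc = make_series(bc_vals, pollutant="BC")
        table = es.size_resolved_correlation(spec, bc)
        assert table.loc[0, "r_mass"] == pytest.approx(1.0)

    def test_independent_noise_bins_uncorrelated(self):
        rng = np.random.default_rng(7)
        n = 200
        ts = pd.date_range("2022-09-26 09:00", periods=n, freq="min")
        edges = np.geomspace(0.25, 32, 31)
        spec = es.SizeSpectrumSeries(ts, edges, rng.lognormal(0, 0.3, (n, 31)))
        bc = make_series(rng.lognormal(1, 0.3, n), pollutant="BC")
        table = es.size_resolved_correlation(spec, bc)
        # null sd of r at n=200 is ~0.07; |r| < 0.2 has probability > 0.99
        assert (table["r_mass"].abs() < 0.2).mean() > 0.9

    def test_planted_bc_loading_ranks_submicron_bins_highest(self, default_campaign):
        series, spectrum = default_campaign
        table = es.size_resolved_correlation(spectrum, series["indoor:BC"])
        top = table.nlargest(5, "r_mass")["bin_low_um"]
        assert (top < 1.0).all()

    def test_unmatched_timestamps_dropped_and_counted(self, default_campaign):
        series, spectrum = default_campaign
        bc = series["indoor:BC"]
        truncated = es.ConcentrationSeries(
            bc.site_id, bc.environment, bc.pollutant,
            bc.timestamps[:-100], bc.values[:-100],
        )
        table = es.size_resolved_correlation(spectrum, truncated)
        assert table["n"].iloc[0] == len(spectrum.timestamps) - 100
        assert table["n_dropped"].iloc[0] == 100

    def test_no_overlap_errors(self, default_campaign):
        _, spectrum = default_campaign
        bc = make_series([1, 2, 3], pollutant="BC", start="1999-01-01")
        with pytest.raises(ValueError, match="overlap"):
            es.size_resolved_correlation(spectrum, bc)


class TestIORatio:
    def _stats(self, mean):
        return es.summarize(make_series([mean] * 4))

    def test_campaign_pm10_excess_near_13_percent(self):
        ratio, excess = es.io_ratio(self._stats(131.29), self._stats(115.86))
        assert round(excess) == 13

    def test_pm1_higher_outdoors(self):
        ratio, excess = es.io_ratio(self._stats(35.83), self._stats(39.28))
        assert ratio == pytest.approx(0.912, abs=5e-4)
        assert excess < 0

    def test_equal_means(self):
        ratio, excess = es.io_ratio(self._stats(10), self._stats(10))
        assert ratio == 1 and excess == 0

    def test_zero_outdoor_errors(self):
        with pytest.raises(ValueError):
            es.io_ratio(self._stats(5), self._stats(0))


class TestAnnualProjection:
    def test_identity_when_annual_equals_study_ambient(self):
        p = es.ProjectionInputs(115.86, 131.29, 115.86)
        assert es.annual_projection(p) == pytest.approx(131.29)

    def test_direct_evaluation(self):
        p = es.ProjectionInputs(80, 131.29, 115.86)
        assert es.annual_projection(p) == pytest.approx(90.65, abs=5e-3)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        c1=st.floats(1, 500), c2=st.floats(1, 500), c3=st.floats(1, 500),
        k=st.floats(0.1, 10),
    )
    def test_homogeneity(self, c1, c2, c3, k):
        base = es.annual_projection(es.ProjectionInputs(c1, c2, c3))
        assert es.annual_projection(es.ProjectionInputs(k * c1, c2, c3)) == pytest.approx(
            k * base, rel=1e-9
        )
        assert es.annual_projection(es.ProjectionInputs(c1, c2, k * c3)) == pytest.approx(
            base / k, rel=1e-9
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            es.ProjectionInputs(0, 1, 1)


class TestDistributionShape:
    def test_normal_draws_select_normal(self):
        rng = np.random.default_rng(11)
        x = np.abs(rng.normal(100, 10, 500))
        assert es.distribution_shape(make_series(x)).selected == "normal"

    def test_skewed_lognormal_draws_select_lognormal(self):
        rng = np.random.default_rng(11)
        x = rng.lognormal(3, 0.8, 500)
        fit = es.distribution_shape(make_series(x))
        assert fit.selected == "lognormal"
        assert fit.loglik_lognormal > fit.loglik_normal

    def test_constant_series_degenerate(self):
        with pytest.raises(es.DegenerateInputError):
            es.distribution_shape(make_series([3.0] * 30))

    def test_nonpositive_values_disable_lognormal(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([[0.0], np.abs(rng.normal(10, 2, 29))])
        fit = es.distribution_shape(make_series(x))
        assert fit.selected == "normal"
        assert fit.loglik_lognormal == -np.inf


class TestSpectrumInvariants:
    def test_aggregation_reproduces_pm_series(self, default_campaign):
        series, spectrum = default_campaign
        for cutoff, key in [(1.0, "indoor:PM1"), (2.5, "indoor:PM2.5"), (10.0, "indoor:PM10")]:
            np.testing.assert_allclose(
                spectrum.aggregate_below(cutoff), series[key].values, rtol=1e-9
            )

    def test_spectrum_requires_31_increasing_bins(self):
        ts = pd.date_range("2022-01-01", periods=2, freq="min")
        with pytest.raises(ValueError, match="31"):
            es.SizeSpectrumSeries(ts, np.arange(5), np.ones((2, 5)))


class TestSeriesInvariants:
    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            make_series([1, -2, 3])

    def test_nonmonotone_timestamps_rejected(self):
        ts = pd.DatetimeIndex(["2022-01-01 10:00", "2022-01-01 09:00"])
        with pytest.raises(ValueError):
            es.ConcentrationSeries("s", "indoor", "PM10", ts, np.array([1.0, 2.0]))


class TestCsvRoundTrip:
    def test_concentration_csv(self, tmp_path, default_campaign):
        series, _ = default_campaign
        path = tmp_path / "conc.csv"
        es.write_concentration_csv(list(series.values()), path)
        back = {f"{s.environment.value}:{s.pollutant}": s for s in es.read_concentration_csv(path)}
        assert set(back) == set(series)
        np.testing.assert_allclose(
            back["indoor:PM10"].values, series["indoor:PM10"].values
        )

    def test_spectrum_csv(self, tmp_path, default_campaign):
        _, spectrum = default_campaign
        path = tmp_path / "spec.csv"
        es.write_spectrum_csv(spectrum, path)
        back = es.read_spectrum_csv(path)
        np.testing.assert_allclose(back.bins, spectrum.bins)
        np.testing.assert_allclose(back.mass, spectrum.mass, rtol=1e-6)
        assert back.number is not None
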