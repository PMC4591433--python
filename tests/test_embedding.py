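import numpy as np
import pytest

from lfpdyn.embedding import (
    autocorrelation,
    average_mutual_information,
    embed,
    first_min_lag,
    first_zero_lag,
    fnn_fraction,
    estimate_lag,
    interpolated_zero_crossing,
)
from lfpdyn.timeseries import TimeSeries

from conftest import sine_series


def fnn_oracle(series, lag, dims, f_ratio, theiler, sigma_mult=2.0):
    """All-pairs brute-force FNN fractions (independent of the KD-tree path)."""
    x = series.values
    n = x.size
    sigma = float(np.std(x))
    out = []
    for d in dims:
        m = n - d * lag
        pts = np.stack([x[j * lag : j * lag + m] for j in range(d)], axis=1)
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        idx = np.arange(m)
        D[np.abs(idx[:, None] - idx[None, :]) <= theiler] = np.inf
        j = np.argmin(D, axis=1)
        rd = D[idx, j]
        valid = np.isfinite(rd)
        i_v, j_v, rd_v = idx[valid], j[valid], rd[valid]
        extra = np.abs(x[i_v + d * lag] - x[j_v + d * lag])
        rd1 = np.sqrt(rd_v**2 + extra**2)
        tiny = rd_v <= 1e-10 * sigma
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(~tiny, extra / np.where(tiny, 1.0, rd_v), 0.0)
        false = (~tiny & (ratio > f_ratio)) | (tiny & (extra > 1e-10 * sigma))
        false |= rd1 > sigma_mult * sigma
        out.append(false.mean())
    return np.array(out)


class TestAutocorrelation:
    def test_periodic_sine_matches_cosine_closed_form(self):
        ts = sine_series(n=4000, period=200)
        acf = autocorrelation(ts, max_lag=400, mode="periodic")
        k = np.arange(401)
        assert np.allclose(acf, np.cos(2 * np.pi * k / 200), atol=1e-10)

    def test_lag_zero_is_one(self, rng):
        ts = TimeSeries(values=rng.normal(size=100), dt=1.0)
        for mode in ("periodic", "linear"):
            assert autocorrelation(ts, 10, mode=mode)[0] == 1.0

    def test_white_noise_stays_within_statistical_bound(self):
        rng = np.random.default_rng(99)
        n = 100_000
        ts = TimeSeries(values=rng.standard_normal(n), dt=1.0)
        acf = autocorrelation(ts, max_lag=20, mode="periodic")
        assert np.all(np.abs(acf[1:]) < 3 / np.sqrt(n))

    def test_constant_series_errors(self):
        with pytest.raises(ValueError):
            autocorrelation(TimeSeries(values=[1.0, 1.0, 1.0], dt=1.0), 2)


class TestFirstZeroLag:
    def test_sine_quarter_period(self):
        ts = sine_series(n=4000, period=200)
        acf = autocorrelation(ts, max_lag=400)
        assert first_zero_lag(acf) == 50
        assert interpolated_zero_crossing(acf) == pytest.approx(50, abs=1)

    def test_all_positive_curve_errors(self):
        with pytest.raises(ValueError, match="max_lag"):
            first_zero_lag(np.array([1.0, 0.9, 0.8, 0.5]))


class TestAverageMutualInformation:
    def test_lag_zero_equals_histogram_entropy(self, rng):
        x = rng.normal(size=5000)
        ts = TimeSeries(values=x, dt=1.0)
        ami = average_mutual_information(ts, max_lag=2, n_bins=16)
        counts, _ = np.histogram(x, bins=16, range=(x.min(), x.max()))
        p = counts[counts > 0] / counts.sum()
        assert ami[0] == pytest.approx(-np.sum(p * np.log(p)), rel=1e-9)

    def test_white_noise_small_sample_bias(self):
        rng = np.random.default_rng(5)
        n, bins = 100_000, 16
        ts = TimeSeries(values=rng.standard_normal(n), dt=1.0)
        ami = average_mutual_information(ts, max_lag=5, n_bins=bins)
        bias = (bins - 1) ** 2 / (2 * n)
        assert np.all(ami[1:] < 3 * bias)
        assert np.all(ami[1:] > bias / 3)

    def test_sine_ami_basin_covers_quarter_period(self):
        """The binned AMI of a sine is minimized in a broad basin around the
        quarter period; the curve's global minimum falls inside it. (The
        *first strict local* minimum is a binning-ripple artifact at small
        lags and is exercised on constructed curves instead.)"""
        ts = sine_series(n=4000, period=200)
        ami = average_mutual_information(ts, max_lag=100)
        k_min = int(np.argmin(ami[1:])) + 1
        assert 35 <= k_min <= 65
        # the basin is genuinely lower than the short-lag region
        assert ami[k_min] < ami[10] < ami[1]


class TestFirstMinLag:
    def test_definition(self):
        assert first_min_lag(np.array([3.0, 2.0, 1.0, 2.0])) == 2

    def test_monotone_curve_errors(self):
        with pytest.raises(ValueError):
            first_min_lag(np.array([3.0, 2.0, 1.0, 0.5]))


class TestEstimateLag:
    def test_prefers_ami_minimum_and_reports_both(self):
        ts = sine_series(n=4000, period=200)
        est = estimate_lag(ts, max_lag=100)
        assert est.acf_first_zero == 50
        assert est.ami_first_min is not None
        assert est.chosen_lag == est.ami_first_min



class TestEmbed:
    def test_dim_one_is_the_series(self, rng):
        ts = TimeSeries(values=rng.normal(size=20), dt=1.0)
        traj = embed(ts, lag=3, dim=1)
        assert traj.points.shape == (20, 1)
        assert np.array_equal(traj.points[:, 0], ts.values)

    def test_point_count_formula(self):
        ts = TimeSeries(values=np.arange(10.0), dt=0.5)
        traj = embed(ts, lag=3, dim=3)
        assert traj.points.shape == (4, 3)
        # window spanned per vector: (d-1)*lag*dt
        assert (traj.dim - 1) * traj.lag * ts.dt == pytest.approx(3.0)
        assert np.array_equal(traj.points[0], [0.0, 3.0, 6.0])

    def test_first_coordinate_reconstructs_series_prefix(self, rng):
        ts = TimeSeries(values=rng.normal(size=50), dt=1.0)
        traj = embed(ts, lag=4, dim=3)
        assert np.array_equal(traj.points[:, 0], ts.values[: traj.points.shape[0]])

    def test_too_short_series_errors(self):
        with pytest.raises(ValueError):
            embed(TimeSeries(values=np.arange(10.0), dt=1.0), lag=5, dim=3)


class TestFnnFraction:
    def test_noise_free_sine_unfolds_in_the_plane(self):
        ts = sine_series(n=4000, period=200)
        curve = fnn_fraction(ts, lag=50, dims=range(1, 4), theiler=10)
        assert curve.fnn_fraction[1] < 0.01

    def test_white_noise_never_unfolds(self):
        rng = np.random.default_rng(0)
        ts = TimeSeries(values=rng.standard_normal(2000), dt=1.0)
        curve = fnn_fraction(ts, lag=1, dims=range(1, 6), theiler=0)
        assert np.all(curve.fnn_fraction[1:] > 0.10)
        assert curve.sigma_criterion_used

    def test_lorenz_dimension_stable_over_ratio_range(self, lorenz10k):
        for f in (7.0, 10.0, 15.0, 20.0):
            curve = fnn_fraction(
                lorenz10k, lag=17, dims=range(1, 6), f_ratio=f, theiler=17
            )
            assert curve.d_E == 3, f"f={f} gave d_E={curve.d_E}"

    @pytest.mark.parametrize("theiler", [0, 3, 10])
    def test_matches_brute_force_oracle(self, lorenz10k, theiler):
        short = TimeSeries(values=lorenz10k.values[:480], dt=lorenz10k.dt)
        dims = range(1, 5)
        fast = fnn_fraction(short, lag=5, dims=dims, f_ratio=8.0, theiler=theiler)
        slow = fnn_oracle(short, lag=5, dims=dims, f_ratio=8.0, theiler=theiler)
        assert np.array_equal(fast.fnn_fraction, slow)

    def test_theiler_window_does_not_reduce_fnn_on_deterministic_data(self, lorenz10k):
        short = TimeSeries(values=lorenz10k.values[:3000], dt=lorenz10k.dt)
        for d in (2, 3):
            base = fnn_fraction(short, lag=17, dims=[d], theiler=0).fnn_fraction[0]
            wide = fnn_fraction(
                short, lag=17, dims=[d], theiler=(d - 1) * 17
            ).fnn_fraction[0]
            assert wide >= base - 1e-12

    def test_decimation_preserves_the_dimension_decision(self, lorenz10k):
        full = fnn_fraction(lorenz10k, lag=18, dims=range(1, 5), theiler=18)
        deci = fnn_fraction(
            lorenz10k, lag=18, dims=range(1, 5), theiler=18, decimate=2
        )
        assert deci.d_E == full.d_E == 3

    def test_insufficient_points_error(self):
        ts = TimeSeries(values=np.arange(30.0), dt=1.0)
        with pytest.raises(ValueError):
            fnn_fraction(ts, lag=10, dims=range(1, 6))
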