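import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lfpdyn.nonlinearity import (
    discriminate,
    fnn_discrimination,
    gamma_avg,
    gamma_cv,
    min_surrogates,
    rank_test,
    time_reversal_asymmetry,
)
from lfpdyn.studies import ar2_series
from lfpdyn.surrogates import SurrogateSet, make_surrogates
from lfpdyn.embedding import autocorrelation, first_zero_lag
from lfpdyn.timeseries import TimeSeries


@pytest.fixture(scope="module")
def ar2_trace() -> TimeSeries:
    return TimeSeries(ar2_series(2048, np.random.default_rng(0)), dt=1.0)


def periodogram(values: np.ndarray) -> np.ndarray:
    return np.abs(np.fft.rfft(values, axis=-1)) ** 2


class TestSurrogates:
    def test_ft_preserves_periodogram(self, ar2_trace):
        s = make_surrogates(ar2_trace, n=20, method="ft", seed=3)
        p0 = periodogram(ar2_trace.values)
        rel = np.abs(periodogram(s.surrogates) - p0) / (p0 + 1e-30 * p0.max())
        assert rel.max() < 1e-8

    @pytest.mark.parametrize("method", ["aaft", "iaaft"])
    def test_amplitude_adjusted_methods_preserve_value_multiset(self, ar2_trace, method):
        s = make_surrogates(ar2_trace, n=10, method=method, seed=4)
        target = np.sort(ar2_trace.values)
        for i in range(s.n):
            assert np.array_equal(np.sort(s.surrogates[i]), target)

    def test_iaaft_approximates_autocorrelation(self, ar2_trace):
        s = make_surrogates(ar2_trace, n=10, method="iaaft", seed=5)
        acf0 = autocorrelation(ar2_trace, 20)
        for i in range(s.n):
            acf_i = autocorrelation(TimeSeries(s.surrogates[i], dt=1.0), 20)
            assert np.max(np.abs(acf_i - acf0)) < 0.05

    def test_reproducible_from_seed(self, ar2_trace):
        a = make_surrogates(ar2_trace, n=5, method="iaaft", seed=11)
        b = make_surrogates(ar2_trace, n=5, method="iaaft", seed=11)
        assert np.array_equal(a.surrogates, b.surrogates)

    def test_constant_series_errors(self):
        flat = TimeSeries(values=np.ones(64), dt=1.0)
        with pytest.raises(ValueError):
            make_surrogates(flat, n=5)

    def test_surrogate_count_rule_for_rank_test(self):
        assert min_surrogates(0.05) == 20
        assert min_surrogates(0.01) == 100


class TestTimeReversalAsymmetry:
    def test_hand_computed_example(self):
        ts = TimeSeries(values=[0.0, 1.0, 3.0], dt=1.0)
        assert time_reversal_asymmetry(ts, delay=1) == pytest.approx(9 / 5)

    def test_sinusoid_is_reversible(self):
        t = np.arange(100_000)
        ts = TimeSeries(values=np.sin(2 * np.pi * t / 1000), dt=1.0)
        assert abs(time_reversal_asymmetry(ts, delay=1)) < 1e-3

    def test_alternating_series_cancels_exactly(self):
        # odd length -> an even number of +1/-1 increments, cubes cancel
        ts = TimeSeries(values=np.tile([0.0, 1.0], 51)[:101], dt=1.0)
        assert time_reversal_asymmetry(ts, delay=1) == 0.0

    def test_constant_series_errors(self):
        with pytest.raises(ValueError):
            time_reversal_asymmetry(TimeSeries(values=np.ones(10), dt=1.0))


class TestGammaScores:
    def test_gamma_avg_zero_when_lambda0_is_the_mean(self):
        assert gamma_avg(2.0, [1.0, 2.0, 3.0]) == pytest.approx(0.0)

    def test_gamma_avg_arithmetic(self):
        assert gamma_avg(0.5, [1.0, 1.5, 2.0]) == pytest.approx(2.0)

    def test_gamma_avg_rejects_zero_lambda0(self):
        with pytest.raises(ValueError):
            gamma_avg(0.0, [1.0])

    def test_gamma_cv_arithmetic(self):
        # two surrogate values with mean 2.0 and sample std 0.5
        d = 0.5 / np.sqrt(2)
        lambdas = [2.0 - d, 2.0 + d]
        assert gamma_cv(0.1893, lambdas) == pytest.approx(3.6214, abs=1e-4)

    def test_gamma_cv_zero_when_lambda0_is_the_mean(self):
        assert gamma_cv(2.0, [1.0, 2.0, 3.0]) == pytest.approx(0.0)

    def test_gamma_cv_rejects_zero_spread(self):
        with pytest.raises(ValueError):
            gamma_cv(1.0, [2.0, 2.0, 2.0])

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(scale=st.floats(min_value=0.01, max_value=100))
    def test_gamma_avg_invariant_under_common_scaling(self, scale):
        lambdas = np.array([0.5, 1.5, 2.5])
        assert gamma_avg(0.7, lambdas) == pytest.approx(
            gamma_avg(0.7 * scale, lambdas * scale), rel=1e-9
        )

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(shift=st.floats(min_value=-100, max_value=100))
    def test_gamma_cv_invariant_under_common_shift(self, shift):
        lambdas = np.array([0.5, 1.5, 2.5])
        assert gamma_cv(0.7, lambdas) == pytest.approx(
            gamma_cv(0.7 + shift, lambdas + shift), rel=1e-9
        )


class TestRankTest:
    def test_extreme_low_rejects(self):
        rank, reject = rank_test(-1.0, list(range(20)))
        assert rank == 1
        assert reject

    def test_median_does_not_reject(self):
        rank, reject = rank_test(10.0, [float(i) for i in range(21) if i != 10])
        assert not reject
        assert 1 < rank < 21

    def test_tie_at_extreme_does_not_reject(self):
        rank, reject = rank_test(0.0, [0.0, 1.0, 2.0, 3.0])
        assert rank == 1
        assert not reject


class TestDiscrimination:
    def test_ml_rhythm_rejects_null(self):
        from lfpdyn.studies import gamma_cv_for_trace
        from lfpdyn.synth import MLParams, simulate_ml_realizations

        trace = simulate_ml_realizations(
            MLParams(), n_traces=1, duration=8.0, dt=5e-4, seed=0
        )[0][400:]
        g = gamma_cv_for_trace(trace, n_surrogates=50, seed=0)
        assert g > 1.96

    def test_discriminate_reports_consistent_scores(self, ar2_trace):
        s = make_surrogates(ar2_trace, n=30, method="iaaft", seed=6)
        res = discriminate(s, delay=3)
        assert res.gamma_cv == pytest.approx(
            gamma_cv(res.lambda0, res.lambdas), rel=1e-12
        )
        assert 1 <= res.rank <= res.n + 1


class TestFnnDiscrimination:
    def test_exchangeable_original_is_not_rejected(self, ar2_trace):
        short = TimeSeries(ar2_trace.values[:600], dt=1.0)
        s = make_surrogates(short, n=8, method="ft", seed=7)
        # swap the original with one of its own surrogates
        swapped = SurrogateSet(
            original=TimeSeries(s.surrogates[0], dt=1.0),
            surrogates=np.vstack([short.values, s.surrogates[1:]]),
            method="ft",
            seed=7,
        )
        res = fnn_discrimination(swapped, lag=3, dims=range(1, 4), theiler=3)
        assert not res.reject

    def test_deterministic_rhythm_rejected_against_ft_surrogates(self):
        from lfpdyn.synth import MLParams, simulate_ml_realizations

        trace = simulate_ml_realizations(
            MLParams(), n_traces=1, duration=1.2, dt=5e-4, seed=0
        )[0][400:]
        ts = TimeSeries(trace, dt=5e-4)
        lag = first_zero_lag(autocorrelation(ts, 500))
        s = make_surrogates(ts, n=50, method="ft", seed=8)
        res = fnn_discrimination(s, lag=lag, dims=range(1, 6), theiler=lag)
        assert res.reject
        assert np.all(res.original_curve < res.surrogate_min)

    def test_linear_process_rarely_rejected(self):
        rng = np.random.default_rng(21)
        rejections = 0
        runs = 8
        for r in range(runs):
            ts = TimeSeries(ar2_series(1200, rng), dt=1.0)
            s = make_surrogates(ts, n=15, method="ft", seed=100 + r)
            res = fnn_discrimination(s, lag=3, dims=range(1, 4), theiler=3)
            rejections += res.reject
        assert rejections <= 1  # >= ~90% of runs retain the null
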