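import numpy as np
import pytest

from hrvperiod.acf import (ACFSeries, DegenerateSeriesError, EmbeddingChoice,
                           autocorrelation, detrend_piecewise, max_acf,
                           mean_acf, se_acf, select_embedding)
from hrvperiod.dataio import ValidationError
from hrvperiod.hrv import sample_entropy


def acf_oracle(x, max_lag):
    """Double-loop evaluation of R(d) = 1/(N-d) sum_n xhat_n xhat_{n+d}."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    xhat = (x - x.mean()) / x.std()  # population SD
    out = []
    for d in range(max_lag + 1):
        acc = 0.0
        for i in range(n - d):
            acc += xhat[i] * xhat[i + d]
        out.append(acc / (n - d))
    return np.array(out)


class TestDetrendPiecewise:
    def test_exact_line_one_segment(self):
        x = 150.0 + 0.5 * np.arange(200)
        ds = detrend_piecewise(x)
        assert np.abs(ds.values).max() < 1e-8
        assert len(ds.segment_bounds) == 2  # just [0, N]

    def test_two_joined_lines_breakpoint_found(self, rng):
        n = 1000
        t = np.arange(n, dtype=float)
        x = np.where(t < 500, t, 1000 - t) + 0.5 * rng.standard_normal(n)
        ds = detrend_piecewise(x)
        interior = ds.segment_bounds[1:-1]
        assert len(interior) >= 1
        assert min(abs(int(b) - 500) for b in interior) <= 10
        assert ds.values.std() < 0.05 * x.std()

    def test_white_noise_nearly_untouched(self, rng):
        x = 170 + 5 * rng.standard_normal(1000)
        ds = detrend_piecewise(x)
        assert ds.values.var() == pytest.approx(x.var(), rel=0.02)

    def test_short_series_single_segment_fallback(self, rng):
        x = 170 + rng.standard_normal(20)
        ds = detrend_piecewise(x, min_segment=30)
        assert len(ds.segment_bounds) == 2

    def test_per_segment_residual_fit_is_flat(self, rng):
        n = 600
        t = np.arange(n, dtype=float)
        x = np.where(t < 300, 2 * t, 600 + 0.5 * (t - 300)) + rng.standard_normal(n)
        ds = detrend_piecewise(x)
        for lo, hi in zip(ds.segment_bounds[:-1], ds.segment_bounds[1:]):
            seg = ds.values[lo:hi]
            slope, intercept = np.polyfit(np.arange(hi - lo, dtype=float), seg, 1)
            assert abs(slope) < 1e-8 * max(1.0, np.abs(x).max())
            assert abs(intercept) < 1e-8 * max(1.0, np.abs(x).max())


class TestAutocorrelation:
    def test_alternating_residuals_closed_form(self):
        x = np.tile([1.0, -1.0], 50)
        acf = autocorrelation(x, max_lag=30)
        np.testing.assert_allclose(acf.values, (-1.0) ** acf.lags, atol=1e-12)

    def test_r0_is_one(self, rng):
        acf = autocorrelation(rng.standard_normal(300), max_lag=50)
        assert acf.values[0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        x = rng.standard_normal(200) + np.sin(np.arange(200) / 3.0)
        acf = autocorrelation(x, max_lag=60)
        np.testing.assert_allclose(acf.values, acf_oracle(x, 60), atol=1e-12)

    def test_iid_noise_small_at_positive_lags(self, rng):
        n = 2000
        acf = autocorrelation(rng.standard_normal(n), max_lag=50)
        inside = np.abs(acf.values[1:]) < 4 / np.sqrt(n)
        assert inside.mean() >= 0.95

    def test_constant_residuals_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            autocorrelation(np.zeros(100), max_lag=10)


class TestAcfSummaries:
    def test_alternating_is_perfectly_periodic(self):
        acf = autocorrelation(np.tile([1.0, -1.0], 100), max_lag=60)
        assert max_acf(acf) == pytest.approx(1.0, abs=1e-9)
        assert mean_acf(acf) == pytest.approx(1.0, abs=1e-9)

    def test_noise_acf_is_small(self, rng):
        acf = autocorrelation(rng.standard_normal(2000), max_lag=60)
        assert max_acf(acf) < 0.1
        assert mean_acf(acf) < 0.05

    def test_sinusoid_period_ten_beats(self):
        x = np.sin(2 * np.pi * np.arange(400) / 10.0)
        acf = autocorrelation(x, max_lag=60)
        assert max_acf(acf) >= 0.95  # ACF peaks at d = 30, 40, 50

    def test_mean_never_exceeds_max(self, rng):
        acf = autocorrelation(rng.standard_normal(500), max_lag=60)
        assert mean_acf(acf) <= max_acf(acf)

    def test_sign_flip_invariance(self, rng):
        x = rng.standard_normal(500)
        a = autocorrelation(x, max_lag=60)
        b = autocorrelation(-x, max_lag=60)
        assert max_acf(a) == pytest.approx(max_acf(b), abs=1e-12)
        assert mean_acf(a) == pytest.approx(mean_acf(b), abs=1e-12)

    def test_range_outside_lags_errors(self, rng):
        acf = autocorrelation(rng.standard_normal(100), max_lag=20)
        with pytest.raises(ValidationError):
            max_acf(acf, (25, 50))


class TestSelectEmbedding:
    def _sin_acf(self, period=20, n_lags=200):
        lags = np.arange(n_lags + 1)
        values = np.cos(2 * np.pi * lags / period)
        return ACFSeries(lags, values)

    def test_sinusoidal_tau_near_quarter_period(self):
        choice = select_embedding(self._sin_acf(period=20))
        assert 4 <= choice.tau <= 6

    def test_sinusoidal_m_small(self):
        choice = select_embedding(self._sin_acf(period=20))
        assert choice.m <= 3

    def test_tolerance_is_fraction_of_acf_sd(self):
        acf = self._sin_acf(period=20)
        choice = select_embedding(acf, tolerance_factor=0.4)
        assert choice.r == pytest.approx(0.4 * np.std(acf.values))

    def test_no_mi_minimum_falls_back_to_tau_one(self, rng):
        # strictly monotone decaying ACF: MI decreases monotonically
        lags = np.arange(201)
        values = np.exp(-lags / 3.0)
        values[0] = 1.0
        choice = select_embedding(ACFSeries(lags, values))
        assert choice.tau == 1

    def test_constant_acf_degenerate(self):
        lags = np.arange(101)
        values = np.ones(101)
        with pytest.raises((DegenerateSeriesError, ValidationError)):
            select_embedding(ACFSeries(lags, values))


class TestSeAcf:
    def test_periodic_acf_near_zero(self):
        x = np.sin(2 * np.pi * np.arange(600) / 10.0)
        acf = autocorrelation(x, max_lag=200)
        value = se_acf(acf)
        assert value is not None and value < 0.05

    def test_noise_like_acf_is_large(self, rng):
        lags = np.arange(201)
        values = np.concatenate([[1.0], 0.5 * rng.standard_normal(200)])
        acf = ACFSeries(lags, values)
        value = se_acf(acf)
        assert value is not None and value > 0.5

    def test_equals_delay_embedded_sampen_oracle(self, rng):
        x = np.sin(2 * np.pi * np.arange(500) / 12.0) + 0.2 * rng.standard_normal(500)
        acf = autocorrelation(x, max_lag=200)
        choice = select_embedding(acf)
        got = se_acf(acf, choice)
        want = sample_entropy(acf.values, m=choice.m, r=choice.r, tau=choice.tau)
        assert got == pytest.approx(want, abs=1e-12)


def test_detrending_rescues_periodicity(rng):
    """A strong drift hides periodicity from the raw ACF; piecewise-linear
    detrending restores the periodic peaks."""
    n = 1000
    t = np.arange(n, dtype=float)
    drift = np.where(t < 500, 0.2 * t, 200 - 0.2 * (t - 500))
    x = drift + 5 * np.sin(2 * np.pi * t / 10.0) + 0.5 * rng.standard_normal(n)
    ds = detrend_piecewise(x)
    acf = autocorrelation(ds, max_lag=60)
    peak_lags = acf.lags[(acf.lags % 10 == 0) & (acf.lags > 0)]
    peaks = np.abs(acf.values[np.isin(acf.lags, peak_lags)])
    assert peaks.max() >= 0.8
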