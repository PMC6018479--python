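import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrvperiod.dataio import ValidationError
from hrvperiod.spectral import (DegenerateSpectrumError, Periodogram,
                                RelativePowerSpectrum, bin_spectrum,
                                default_freq_grid, lomb_scargle, max_per,
                                relative_spectrum, sliding_spectrogram, trse)


def ls_oracle(t, x, freqs):
    """Direct evaluation of the classical Lomb-Scargle formula."""
    out = []
    for f in freqs:
        w = 2 * np.pi * f
        tau = np.arctan2(np.sum(np.sin(2 * w * t)), np.sum(np.cos(2 * w * t))) / (2 * w)
        c = np.cos(w * (t - tau))
        s = np.sin(w * (t - tau))
        out.append(0.5 * ((x @ c) ** 2 / (c @ c) + (x @ s) ** 2 / (s @ s)))
    return np.array(out)


class TestLombScargle:
    def test_single_tone_peak_location(self):
        t = np.arange(500) / 5.0
        y = np.sin(2 * np.pi * 1.0 * t)
        grid = np.linspace(0.3, 2.0, 500)
        pg = lomb_scargle(t, y, grid)
        step = grid[1] - grid[0]
        assert abs(grid[pg.power.argmax()] - 1.0) <= step

    def test_uneven_sampling_keeps_peak(self, rng):
        t = np.arange(500) / 5.0
        keep = rng.uniform(size=500) > 0.3  # delete 30% of samples
        y = np.sin(2 * np.pi * 1.0 * t)
        grid = np.linspace(0.3, 2.0, 500)
        pg = lomb_scargle(t[keep], y[keep], grid)
        step = grid[1] - grid[0]
        assert abs(grid[pg.power.argmax()] - 1.0) <= step

    def test_matches_direct_formula_oracle(self, rng):
        t = np.sort(rng.uniform(0, 100, 300))
        y = np.sin(2 * np.pi * 1.3 * t) + 0.5 * rng.standard_normal(300)
        freqs = np.sort(rng.uniform(0.1, 2.0, 20))
        pg = lomb_scargle(t, y, freqs)
        want = ls_oracle(t, y - y.mean(), freqs)
        np.testing.assert_allclose(pg.power, want, atol=1e-9)

    def test_rejects_nonpositive_frequencies(self):
        t = np.arange(10.0)
        with pytest.raises(ValidationError):
            lomb_scargle(t, np.sin(t), np.array([0.0, 0.5]))


class TestRelativeSpectrum:
    def test_normalizes_to_one(self, rng):
        pg = Periodogram(np.linspace(0.1, 3.0, 100), rng.uniform(size=100))
        rs = relative_spectrum(pg)
        assert rs.relpower.sum() == pytest.approx(1.0, abs=1e-12)

    def test_sub_band_power_excluded(self):
        freqs = np.array([0.1, 1.0])
        pg = Periodogram(freqs, np.array([100.0, 1.0]))
        rs = relative_spectrum(pg)
        # all power below 0.3 Hz is dropped before normalization
        assert rs.relpower == pytest.approx([1.0])
        assert rs.freqs == pytest.approx([1.0])

    def test_two_component_arithmetic(self):
        pg = Periodogram(np.array([0.5, 1.5]), np.array([2.0, 6.0]))
        rs = relative_spectrum(pg)
        np.testing.assert_allclose(rs.relpower, [0.25, 0.75])

    def test_full_spectrum_normalization_variant(self):
        pg = Periodogram(np.array([0.1, 0.5, 1.5]), np.array([2.0, 2.0, 6.0]))
        rs = relative_spectrum(pg, normalization="full")
        # denominators include the excluded 0.1 Hz component
        np.testing.assert_allclose(rs.relpower, [0.2, 0.6])
        # tRSE renormalizes in-band, so both variants agree
        assert trse(rs) == pytest.approx(trse(relative_spectrum(pg)), abs=1e-12)

    def test_zero_in_band_power_raises(self):
        pg = Periodogram(np.array([0.5, 1.5]), np.array([0.0, 0.0]))
        with pytest.raises(DegenerateSpectrumError):
            relative_spectrum(pg)


class TestMaxPer:
    def test_flat_spectrum(self):
        k = 40
        rs = RelativePowerSpectrum(np.linspace(0.3, 2, k), np.full(k, 1 / k),
                                   (0.3, 2.0))
        assert max_per(rs) == pytest.approx(1 / k)

    def test_delta_spectrum(self):
        p = np.zeros(40)
        p[10] = 1.0
        rs = RelativePowerSpectrum(np.linspace(0.3, 2, 40), p, (0.3, 2.0))
        assert max_per(rs) == 1.0


class TestTrse:
    def _rs(self, relpower):
        relpower = np.asarray(relpower, dtype=float)
        freqs = np.linspace(0.3001, 1.9999, len(relpower))
        return RelativePowerSpectrum(freqs, relpower, (0.3, 2.0))

    def test_one_bin_gives_one(self):
        p = np.zeros(100)
        p[3] = 1.0  # all power inside the first of 20 bins
        assert trse(self._rs(p)) == pytest.approx(1.0)

    def test_uniform_gives_zero(self):
        # one grid point at each of the 20 bin centers, equal power
        width = (2.0 - 0.3) / 20
        centers = 0.3 + width * (np.arange(20) + 0.5)
        rs = RelativePowerSpectrum(centers, np.full(20, 1 / 20), (0.3, 2.0))
        assert trse(rs) == pytest.approx(0.0, abs=1e-12)

    def test_two_equal_bins_closed_form(self):
        p = np.zeros(100)
        p[2] = 0.5   # bin 0
        p[97] = 0.5  # bin 19
        assert trse(self._rs(p)) == pytest.approx(1 - np.log(2) / np.log(20))

    def test_scale_invariance_through_normalization(self, rng):
        power = rng.uniform(size=200)
        freqs = np.linspace(0.3, 2.0, 200)
        a = trse(relative_spectrum(Periodogram(freqs, power)))
        b = trse(relative_spectrum(Periodogram(freqs, 7.3 * power)))
        assert a == pytest.approx(b, abs=1e-12)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_entropy_bound(self, seed):
        rng = np.random.default_rng(seed)
        power = rng.exponential(size=80)
        rs = relative_spectrum(Periodogram(np.linspace(0.3, 2.0, 80), power))
        for bins in (10, 20):
            assert 0.0 <= trse(rs, bins) <= 1.0

    def test_bin_power_sums_to_one(self, rng):
        rs = relative_spectrum(
            Periodogram(np.linspace(0.3, 2.0, 123), rng.uniform(size=123)))
        bs = bin_spectrum(rs, 20)
        assert bs.bin_power.sum() == pytest.approx(1.0, abs=1e-9)
        assert len(bs.bin_power) == 20


class TestSlidingSpectrogram:
    def test_chirp_argmax_increases(self):
        fs = 5.0
        t = np.arange(0, 300, 1 / fs)
        # sweep 0.5 -> 1.5 Hz over 300 s
        phase = 2 * np.pi * (0.5 * t + 0.5 * t**2 / 600)
        y = np.sin(phase)
        grid = np.linspace(0.3, 2.0, 400)
        result = sliding_spectrogram(t, y, window_s=60, step_s=30, freq_grid=grid)
        peaks = [pg.freqs[pg.power.argmax()] for _, pg in result]
        assert len(peaks) >= 5
        assert all(a < b for a, b in zip(peaks, peaks[1:]))

    def test_stationary_tone_argmax_constant(self):
        t = np.arange(0, 300, 0.2)
        y = np.sin(2 * np.pi * 1.0 * t)
        grid = np.linspace(0.3, 2.0, 400)
        result = sliding_spectrogram(t, y, window_s=60, step_s=60, freq_grid=grid)
        peaks = {round(pg.freqs[pg.power.argmax()], 2) for _, pg in result}
        assert len(peaks) == 1

    def test_short_record_empty(self):
        t = np.arange(0, 10, 0.2)
        out = sliding_spectrogram(t, np.sin(t), window_s=60, step_s=30,
                                  freq_grid=np.linspace(0.3, 2, 50))
        assert out == []


def test_default_freq_grid_spacing_and_coverage():
    grid = default_freq_grid(100.0, (0.3, 2.0), oversample=4)
    assert grid[0] == pytest.approx(0.3)
    assert grid[-1] >= 2.0 - 1e-9
    assert np.allclose(np.diff(grid)[:-1], 1 / 400.0)
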