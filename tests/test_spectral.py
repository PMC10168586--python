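"""Spectral pipeline: binning, Welch estimation, beta scalars, bias
correction, time-resolved analysis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal

from bgbeta.network import SpikeRaster
from bgbeta.spectral import (
    BETA_HIGH,
    BETA_LOW,
    RateSeries,
    Spectrum,
    WELCH_KW,
    bin_rates,
    beta_power_skewness,
    binomial_null,
    corrected_beta_psd,
    mean_beta_psd,
    mean_frequency,
    time_resolved,
    welch_psd,
)


def make_raster(times, ids, pops={"P": (0, 10)}, duration=1000.0):
    return SpikeRaster(np.asarray(times, float), np.asarray(ids), pops,
                       duration, 0.0)


def flat_spectrum(level=1.0, df=0.5):
    freqs = np.arange(0.0, 500.0 + df / 2, df)
    return Spectrum("x", freqs, np.full_like(freqs, level))


class TestBinning:
    def test_empty_raster_all_zero(self):
        series = bin_rates(make_raster([], []), "P")
        assert series.counts.sum() == 0
        assert series.counts.size == 1000

    def test_periodic_raster_and_time_translation(self):
        """One neuron firing every 10 ms gives a 100 Hz mean rate and
        1/0 bins with period 10; shifting spike times by one period
        leaves every spectral scalar unchanged."""
        t = np.arange(5.0, 1000.0, 10.0)
        s1 = bin_rates(make_raster(t, np.zeros(t.size, int)), "P")
        assert s1.mean_rate * s1.n_observed == pytest.approx(100.0, rel=0.01)
        nz = np.flatnonzero(s1.counts)
        assert np.all(np.diff(nz) == 10)
        t2 = (t + 10.0) % 1000.0
        s2 = bin_rates(make_raster(t2, np.zeros(t.size, int)), "P")
        np.testing.assert_array_equal(np.sort(s1.counts), np.sort(s2.counts))

    def test_neuron_relabeling_invariance(self, rng):
        times = np.sort(rng.uniform(0, 1000, 400))
        ids = rng.integers(0, 10, 400)
        s1 = bin_rates(make_raster(times, ids), "P")
        perm = rng.permutation(10)
        s2 = bin_rates(make_raster(times, perm[ids]), "P")
        np.testing.assert_array_equal(s1.counts, s2.counts)

    def test_poisson_raster_mean(self, rng):
        """Poisson spikes at nu0 per neuron: per-bin mean ~ N*nu0*1ms."""
        N, rate_hz, T = 50, 20.0, 4000.0
        n = rng.poisson(rate_hz * T / 1000.0 * N)
        times = np.sort(rng.uniform(0, T, n))
        ids = rng.integers(0, N, n)
        series = bin_rates(make_raster(times, ids, {"P": (0, N)}, T), "P")
        lam = N * rate_hz / 1000.0
        se = np.sqrt(lam / series.counts.size)
        assert abs(series.counts.mean() - lam) < 3 * se

    def test_unknown_population(self):
        with pytest.raises(KeyError):
            bin_rates(make_raster([], []), "Q")


class TestWelch:
    def test_sinusoid_peak_at_13hz(self):
        t = np.arange(10000) / 1000.0
        series = RateSeries("x", 5 + np.sin(2 * np.pi * 13.0 * t), 10)
        spec = welch_psd(series)
        assert spec.freqs[np.argmax(spec.psd)] == pytest.approx(13.0, abs=0.5)
        assert spec.mean_f == pytest.approx(13.0, abs=0.3)

    def test_welch_equals_mean_of_nine_segments(self, rng):
        """The 2000/1000 segmentation of a 10 000-sample series averages
        exactly 9 tapered periodograms."""
        x = rng.normal(size=10000)
        series = RateSeries("x", x, 10)
        spec = welch_psd(series)
        win = signal.get_window(("tukey", 0.25), 2000)
        segs = []
        for k in range(9):
            seg = x[k * 1000:k * 1000 + 2000]
            f, p = signal.periodogram(
                seg, fs=1000.0, window=win, detrend="constant",
                scaling="density",
            )
            segs.append(p)
        np.testing.assert_allclose(spec.psd, np.mean(segs, axis=0), rtol=1e-10)

    def test_white_noise_level_matches_parseval(self, rng):
        """I.i.d. noise of variance sigma^2 has a flat one-sided density
        2 sigma^2 / fs."""
        sigma2 = 4.0
        series = RateSeries("x", rng.normal(0, 2.0, 200_000), 10)
        spec = welch_psd(series)
        level = 2 * sigma2 / 1000.0
        inner = (spec.freqs > 20) & (spec.freqs < 480)
        assert spec.psd[inner].mean() == pytest.approx(level, rel=0.05)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            welch_psd(RateSeries("x", np.zeros(1500), 10))


class TestBetaScalars:
    def test_flat_spectrum_mean_frequency_is_band_midpoint(self):
        assert mean_frequency(flat_spectrum()) == pytest.approx(16.0, abs=1e-9)

    def test_delta_spectrum(self):
        spec = flat_spectrum(0.0)
        spec.psd[spec.freqs == 13.0] = 5.0
        assert mean_frequency(spec) == pytest.approx(13.0, abs=0.1)

    def test_linear_spectrum_closed_form(self):
        """P(f) = f on [8, 24]: mean f = (int f^2)/(int f) = 17.333 Hz."""
        freqs = np.arange(0.0, 500.0, 0.5)
        spec = Spectrum("x", freqs, freqs.copy())
        assert mean_frequency(spec) == pytest.approx(52.0 / 3.0, rel=1e-3)

    def test_mean_beta_psd_flat_and_zero(self):
        assert mean_beta_psd(flat_spectrum(3.7)) == pytest.approx(3.7, rel=1e-9)
        assert mean_beta_psd(flat_spectrum(0.0)) == 0.0

    def test_narrowband_peak_area(self):
        """A peak of known integrated area A gives Mean PSD = A/(M-m)."""
        spec = flat_spectrum(0.0)
        df = spec.freqs[1] - spec.freqs[0]
        spec.psd[(spec.freqs >= 12) & (spec.freqs <= 14)] = 2.0
        area = np.trapezoid(spec.psd[(spec.freqs >= 8) & (spec.freqs <= 24)],
                            dx=df)
        assert mean_beta_psd(spec) == pytest.approx(area / 16.0, rel=1e-9)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(0, 10_000))
    def test_mean_frequency_bounded_by_band(self, seed):
        rng = np.random.default_rng(seed)
        freqs = np.arange(0.0, 500.0, 0.5)
        spec = Spectrum("x", freqs, rng.uniform(0, 1, freqs.size))
        assert BETA_LOW <= mean_frequency(spec) <= BETA_HIGH

    def test_zero_band_power_undefined(self):
        assert np.isnan(mean_frequency(flat_spectrum(0.0)))


class TestBinomialNull:
    def test_zero_rate(self):
        assert binomial_null(0.0, 100, 10000.0) == (0.0, 0.0)

    def test_invalid_nu0(self):
        with pytest.raises(ValueError):
            binomial_null(1.2, 100, 10000.0)

    def test_corrected_psd_of_surrogate_is_zero(self, rng):
        """PSD† of a binomial surrogate evaluated against its own null is
        statistically indistinguishable from 0 (checked over repeats)."""
        N, nu0, T = 400, 0.05, 10000.0
        vals = []
        for rep in range(20):
            counts = rng.binomial(N, nu0, int(T)).astype(float)
            spec = welch_psd(RateSeries("x", counts, N))
            Q, Q_se = binomial_null(nu0, N, T, n_rep=12, seed=rep)
            vals.append(corrected_beta_psd(spec, Q))
        from scipy import stats
        t, p = stats.ttest_1samp(vals, 0.0)
        assert p > 0.01

    def test_null_matches_analytic_white_level(self):
        """Q equals the flat density 2 N nu0 (1-nu0) / fs of an i.i.d.
        binomial series under the shared normalization."""
        N, nu0 = 400, 0.05
        Q, Q_se = binomial_null(nu0, N, 20000.0, n_rep=20, seed=5)
        level = 2 * N * nu0 * (1 - nu0) / 1000.0
        assert Q == pytest.approx(level, rel=0.1)


class TestTimeResolved:
    def test_stationary_sinusoid_constant_frequency(self):
        t = np.arange(10000) / 1000.0
        series = RateSeries("x", 5 + np.sin(2 * np.pi * 13.0 * t), 10)
        res = time_resolved(series)
        assert np.allclose(res["mean_f"], 13.0, atol=0.4)

    def test_two_epoch_frequency_switch(self):
        """13 Hz followed by 19 Hz: the instantaneous mean frequency
        switches level at the boundary within one window length."""
        t = np.arange(5000) / 1000.0
        x = np.concatenate([
            5 + np.sin(2 * np.pi * 13.0 * t),
            5 + np.sin(2 * np.pi * 19.0 * t),
        ])
        res = time_resolved(RateSeries("x", x, 10))
        early = res["mean_f"][res["times"] < 4000]
        late = res["mean_f"][res["times"] > 6000]
        assert np.allclose(early, 13.0, atol=0.5)
        assert np.allclose(late, 19.0, atol=0.5)

    def test_window_longer_than_series(self):
        with pytest.raises(ValueError):
            time_resolved(RateSeries("x", np.zeros(1000), 10), window=2000.0)


class TestSkewness:
    def test_symmetric_sample_near_zero(self, rng):
        assert abs(beta_power_skewness(rng.normal(size=20000))) < 0.1

    def test_exponential_sample_near_two(self, rng):
        """The exponential distribution has skewness 2."""
        x = rng.exponential(size=50000)
        assert beta_power_skewness(x) == pytest.approx(2.0, abs=0.15)

    def test_degenerate_input_undefined(self):
        assert np.isnan(beta_power_skewness(np.full(100, 3.3)))
        assert np.isnan(beta_power_skewness([1.0, 2.0]))
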