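"""Resampling, filtering, band power, RP and ERSP against analytic and
brute-force oracles."""

import numpy as np
import pytest

from brainswitch.signal_io import (BlockParams, EpochSet, EventSchedule,
                                   Recording)
from brainswitch.spectral import (ERSPMap, PowerSeries, band_power,
                                  band_topography, bandpass,
                                  moving_average_power, relative_potential,
                                  resample, ersp)


def _rec(x, rate, labels=None):
    x = np.atleast_2d(x)
    labels = labels or [f"ch{i}" for i in range(x.shape[0])]
    return Recording(x, rate, labels)


class TestResample:
    def test_downsample_length(self, rng):
        rec = _rec(rng.standard_normal(5120), 512.0)
        out = resample(rec, 64.0)
        assert out.rate == 64.0
        assert out.n_samples == 640

    def test_identity_when_rates_match(self, rng):
        rec = _rec(rng.standard_normal(640), 64.0)
        out = resample(rec, 64.0)
        np.testing.assert_array_equal(out.samples, rec.samples)

    def test_sinusoid_amplitude_preserved(self):
        t = np.arange(5120) / 512.0
        rec = _rec(np.sin(2 * np.pi * 5 * t), 512.0)
        out = resample(rec, 64.0)
        mid = out.samples[0, 100:-100]
        assert abs(mid.max() - 1.0) < 0.01

    def test_invalid_rate(self, rng):
        with pytest.raises(ValueError):
            resample(_rec(rng.standard_normal(64), 64.0), 0.0)


class TestBandpass:
    def test_out_of_band_tone_attenuated_40db(self):
        rate = 128.0
        t = np.arange(int(20 * rate)) / rate
        x = np.sin(2 * np.pi * 10 * t) + np.sin(2 * np.pi * 40 * t)
        out = bandpass(_rec(x, rate), (8.0, 12.0)).samples[0]
        spec = np.abs(np.fft.rfft(out * np.hanning(len(out))))
        freqs = np.fft.rfftfreq(len(out), 1 / rate)
        p10 = spec[np.argmin(np.abs(freqs - 10))]
        p40 = spec[np.argmin(np.abs(freqs - 40))]
        assert 20 * np.log10(p10 / p40) >= 40.0

    def test_zero_input_zero_output(self):
        out = bandpass(_rec(np.zeros(1024), 64.0), (8.0, 12.0))
        np.testing.assert_array_equal(out.samples, 0.0)

    def test_zero_phase(self):
        """An in-band tone keeps its phase (no group delay)."""
        rate = 64.0
        t = np.arange(int(30 * rate)) / rate
        x = np.sin(2 * np.pi * 10 * t)
        y = bandpass(_rec(x, rate), (8.0, 12.0)).samples[0]
        mid = slice(300, -300)
        r = np.corrcoef(x[mid], y[mid])[0, 1]
        assert r > 0.999

    def test_idempotent_for_in_band_content(self):
        """Refiltering changes a mid-band tone by well under the stop-band
        tolerance."""
        rate = 64.0
        t = np.arange(int(60 * rate)) / rate
        rec = _rec(np.sin(2 * np.pi * 10 * t), rate)
        once = bandpass(rec, (8.0, 12.0))
        twice = bandpass(once, (8.0, 12.0))
        mid = slice(512, -512)
        err = np.abs(twice.samples[0, mid] - once.samples[0, mid])
        assert err.max() < 0.01

    @pytest.mark.parametrize("band", [(12.0, 8.0), (8.0, 8.0), (8.0, 40.0)])
    def test_invalid_bands(self, rng, band):
        with pytest.raises(ValueError):
            bandpass(_rec(rng.standard_normal(256), 64.0), band)


class TestBandPower:
    def test_sinusoid_steady_state_half_amplitude_squared(self):
        rate, a = 64.0, 3.0
        t = np.arange(int(30 * rate)) / rate
        ps = band_power(_rec(a * np.sin(2 * np.pi * 10 * t), rate))[0]
        mid = ps.values[200:-200]
        assert np.abs(mid.mean() - a * a / 2).max() < 0.05 * a * a / 2

    def test_zero_signal(self):
        ps = band_power(_rec(np.zeros(640), 64.0))[0]
        np.testing.assert_array_equal(ps.values, 0.0)

    def test_halving_amplitude_quarters_power(self):
        rate = 64.0
        t = np.arange(int(30 * rate)) / rate
        full = band_power(_rec(np.sin(2 * np.pi * 10 * t), rate))[0]
        half = band_power(_rec(0.5 * np.sin(2 * np.pi * 10 * t), rate))[0]
        ratio = half.values[200:-200].mean() / full.values[200:-200].mean()
        assert ratio == pytest.approx(0.25, rel=1e-9)

    def test_matches_plain_moving_average_oracle(self, rng):
        x = rng.standard_normal(500)
        got = moving_average_power(x, 64.0, smooth_s=0.25)
        size = 16
        # brute-force centered moving average of the squared signal
        padded = np.pad(x ** 2, (size, size), mode="edge")
        want = np.array([padded[i + size - size // 2 + 1:
                                i + size + size - size // 2 + 1].mean()
                         for i in range(len(x))])
        # uniform_filter1d centers even windows half a sample differently;
        # compare against both centerings
        want2 = np.array([padded[i + size - size // 2:
                                 i + size + size - size // 2].mean()
                          for i in range(len(x))])
        assert (np.allclose(got, want, atol=1e-12)
                or np.allclose(got, want2, atol=1e-12))

    def test_negative_smoothing_rejected(self, rng):
        with pytest.raises(ValueError):
            moving_average_power(rng.standard_normal(64), 64.0, smooth_s=-1)


class TestRelativePotential:
    def test_equal_power_is_zero(self):
        ps = PowerSeries(np.full(10, 4.0), 64.0, (8, 12))
        np.testing.assert_allclose(relative_potential(ps, 4.0), 0.0)

    def test_half_power_is_minus_fifty(self):
        ps = PowerSeries(np.full(10, 2.0), 64.0, (8, 12))
        np.testing.assert_allclose(relative_potential(ps, 4.0), -50.0)

    def test_amplitude_halving_gives_minus_75(self):
        """Power scales with amplitude^2, so a/2 -> RP = -75 %."""
        rate = 64.0
        t = np.arange(int(40 * rate)) / rate
        amp = np.where(t < 20, 1.0, 0.5)
        ps = band_power(_rec(amp * np.sin(2 * np.pi * 10 * t), rate))[0]
        baseline = ps.values[200:1100].mean()
        second_half = relative_potential(
            PowerSeries(ps.values[1500:2400], rate, (8, 12)), baseline)
        assert abs(second_half.mean() + 75.0) < 2.0

    def test_scale_invariance(self, rng):
        """RP is unchanged when raw amplitude rescales (A, R scale together)."""
        x = rng.standard_normal(2000)
        for c in (0.1, 7.3):
            p1 = moving_average_power(x, 64.0)
            p2 = moving_average_power(c * x, 64.0)
            rp1 = relative_potential(PowerSeries(p1, 64.0, (0, 0)),
                                     p1[:100].mean())
            rp2 = relative_potential(PowerSeries(p2, 64.0, (0, 0)),
                                     p2[:100].mean())
            np.testing.assert_allclose(rp1, rp2, atol=1e-8)

    def test_nonpositive_baseline_rejected(self):
        ps = PowerSeries(np.ones(4), 64.0, (8, 12))
        with pytest.raises(ValueError):
            relative_potential(ps, 0.0)


def _epochs_from_signal(x, rate=64.0, n_trials=2, labels=None):
    x = np.atleast_2d(x)
    labels = labels or [f"ch{i}" for i in range(x.shape[0])]
    eps = np.stack([x] * n_trials)
    return EpochSet(eps, rate, labels, (-4.0, 4.0))


def _ersp_oracle(epochs, freqs, baseline=(-4.0, -2.0), win_s=1.0,
                 overlap=0.97):
    """Direct per-window DFT ERSP, nothing shared with the implementation."""
    rate = epochs.rate
    n_win = int(round(win_s * rate))
    hop = max(1, int(round((1 - overlap) * n_win)))
    taper = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(n_win) / n_win)
    n_tr, n_ch, n_t = epochs.epochs.shape
    starts = list(range(0, n_t - n_win + 1, hop))
    times = (np.array(starts) + n_win / 2 - epochs.cue_index) / rate
    out = np.empty((n_ch, len(freqs), len(starts)))
    for c in range(n_ch):
        for fi, f in enumerate(freqs):
            k = round(f * n_win / rate)  # nearest DFT bin
            basis = np.exp(-2j * np.pi * k * np.arange(n_win) / n_win)
            for si, s in enumerate(starts):
                acc = 0.0
                for tr in range(n_tr):
                    seg = epochs.epochs[tr, c, s:s + n_win] * taper
                    acc += np.abs(np.sum(seg * basis)) ** 2
                out[c, fi, si] = acc / n_tr
    sel = (times >= baseline[0]) & (times < baseline[1])
    logp = 10 * np.log10(out)
    return logp - logp[..., sel].mean(axis=-1, keepdims=True), times


class TestERSP:
    def test_stationary_signal_is_flat(self):
        """No task modulation -> the normalization cancels everything."""
        rate = 64.0
        t = np.arange(512) / rate - 4.0
        x = np.sin(2 * np.pi * 10 * t)
        emap = ersp(_epochs_from_signal(x, n_trials=2),
                    freqs=np.arange(9.0, 12.0))
        assert np.abs(emap.power).max() < 0.5

    def test_amplitude_halved_during_task_is_minus_6db(self):
        rate = 64.0
        t = np.arange(512) / rate - 4.0
        env = np.where((t >= 0) & (t < 2), 0.5, 1.0)
        x = env * np.sin(2 * np.pi * 10 * t)
        emap = ersp(_epochs_from_signal(x), freqs=np.array([10.0]))
        sel = (emap.times >= 0.6) & (emap.times < 1.4)
        got = emap.power[0, 0, sel].mean()
        assert got == pytest.approx(10 * np.log10(0.25), abs=0.3)

    def test_matches_direct_dft_oracle(self, rng):
        rate = 64.0
        x = rng.standard_normal((2, 512))
        eps = EpochSet(rng.standard_normal((2, 2, 512)), rate,
                       ["a", "b"], (-4.0, 4.0))
        freqs = np.array([8.0, 10.0, 13.0])
        emap = ersp(eps, freqs=freqs)
        want, times = _ersp_oracle(eps, freqs)
        np.testing.assert_allclose(emap.times, times)
        np.testing.assert_allclose(emap.power, want, rtol=1e-9, atol=1e-9)

    def test_baseline_interval_mean_is_zero(self, rng):
        eps = EpochSet(rng.standard_normal((3, 2, 512)), 64.0,
                       ["a", "b"], (-4.0, 4.0))
        emap = ersp(eps, freqs=np.arange(8.0, 13.0))
        sel = (emap.times >= -4.0) & (emap.times < -2.0)
        base_mean = emap.power[..., sel].mean(axis=-1)
        assert np.abs(base_mean).max() < 1e-6

    def test_baseline_outside_epoch_rejected(self, rng):
        eps = EpochSet(rng.standard_normal((2, 1, 256)), 64.0, ["a"],
                       (-2.0, 2.0))
        with pytest.raises(ValueError):
            ersp(eps, baseline=(-4.0, -2.0))


class TestBandTopography:
    def _flat_map(self, value=-3.0):
        freqs = np.arange(8.0, 13.0)
        times = np.linspace(-3.5, 3.5, 20)
        power = np.full((3, len(freqs), len(times)), value)
        return ERSPMap(power, freqs, times, ["C3", "Cz", "O1"])

    def test_constant_map(self):
        topo = band_topography(self._flat_map(-3.0), (8, 12), (0, 2))
        assert topo == {"C3": -3.0, "Cz": -3.0, "O1": -3.0}

    def test_band_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            band_topography(self._flat_map(), (20, 28), (0, 2))

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError):
            band_topography(self._flat_map(), (8, 12), (5.0, 6.0))
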