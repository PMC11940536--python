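"""Unit and property tests for PSD, band energies and weight identification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ssvepsim.core import TimeSeries
from ssvepsim.spectral import (
    DEFAULT_BANDS,
    BandTable,
    Spectrum,
    band_energies,
    compute_psd,
    dominant_frequency,
    identify_weights,
    spectral_centroid,
)


def _sine(freq, fs=1024.0, n=4096, amp=1.0):
    t = np.arange(n) / fs
    return TimeSeries(fs=fs, values=amp * np.sin(2 * np.pi * freq * t))


class TestComputePSD:
    def test_sinusoid_peak_bin(self):
        s = compute_psd(_sine(10.0))
        assert s.peak_frequency() == pytest.approx(10.0)

    def test_constant_signal_zero_psd(self):
        s = compute_psd(TimeSeries(fs=256.0, values=np.full(512, 3.7)))
        assert np.allclose(s.power, 0.0)

    def test_parseval_white_noise(self, rng):
        x = rng.normal(0, 2.0, 4096)
        ts = TimeSeries(fs=512.0, values=x)
        s = compute_psd(ts)
        total = np.sum(s.power) * s.df
        assert total == pytest.approx(np.var(x), rel=1e-6)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            compute_psd(TimeSeries(fs=10.0, values=np.array([1.0])))


class TestBandEnergies:
    def test_flat_psd_energies_proportional_to_widths(self):
        freqs = np.arange(0.0, 128.0, 0.5)
        s = Spectrum(freqs=freqs, power=np.ones_like(freqs))
        e = band_energies(s)
        # bin counts per band at 0.5 Hz spacing: widths 4:4:8:16:32
        assert e["theta"] == pytest.approx(e["delta"])
        assert e["alpha"] == pytest.approx(2 * e["delta"])
        assert e["beta"] == pytest.approx(4 * e["delta"])
        assert e["gamma"] == pytest.approx(8 * e["delta"])

    def test_single_bin_in_alpha(self):
        freqs = np.arange(0.0, 128.0, 1.0)
        power = np.zeros_like(freqs)
        power[10] = 5.0  # 10 Hz
        e = band_energies(Spectrum(freqs=freqs, power=power))
        assert e["alpha"] == pytest.approx(5.0)
        assert sum(v for k, v in e.items() if k != "alpha") == 0.0

    def test_half_open_boundaries(self):
        # 4, 16 and 32 Hz belong to the upper band of each printed overlap
        freqs = np.arange(0.0, 128.0, 1.0)
        for f, band in [(4.0, "theta"), (8.0, "alpha"), (16.0, "beta"), (32.0, "gamma")]:
            power = np.zeros_like(freqs)
            power[int(f)] = 1.0
            e = band_energies(Spectrum(freqs=freqs, power=power))
            assert e[band] == pytest.approx(1.0), f"{f} Hz should fall in {band}"

    @given(
        arrays(np.float64, 257, elements=st.floats(min_value=0, max_value=1e3)),
    )
    @settings(deadline=None, max_examples=50)
    def test_matches_bruteforce_loop(self, power):
        freqs = np.linspace(0.0, 128.0, 257)
        s = Spectrum(freqs=freqs, power=power)
        e = band_energies(s)
        for band in DEFAULT_BANDS:
            brute = sum(
                p for f, p in zip(freqs, power) if band.lo <= f < band.hi
            )
            assert e[band.label] == pytest.approx(brute, rel=1e-12, abs=1e-12)

    def test_insufficient_coverage_rejected(self):
        freqs = np.arange(0.0, 30.0, 1.0)
        with pytest.raises(ValueError):
            band_energies(Spectrum(freqs=freqs, power=np.ones_like(freqs)))


class TestIdentifyWeights:
    def test_flat_psd_ratio(self):
        freqs = np.arange(0.0, 128.0, 0.5)
        s = Spectrum(freqs=freqs, power=np.ones_like(freqs))
        w = identify_weights(s)
        # band widths 4 : 8 : 32 over their 44 Hz total
        assert w.w_delta == pytest.approx(4 / 44, rel=1e-3)
        assert w.w_alpha == pytest.approx(8 / 44, rel=1e-3)
        assert w.w_gamma == pytest.approx(32 / 44, rel=1e-3)

    def test_pure_alpha(self):
        freqs = np.arange(0.0, 128.0, 1.0)
        power = np.zeros_like(freqs)
        power[12] = 1.0
        w = identify_weights(Spectrum(freqs=freqs, power=power))
        assert (w.w_delta, w.w_alpha, w.w_gamma) == (0.0, 1.0, 0.0)

    def test_zero_energy_rejected(self):
        freqs = np.arange(0.0, 128.0, 1.0)
        with pytest.raises(ValueError):
            identify_weights(Spectrum(freqs=freqs, power=np.zeros_like(freqs)))

    @given(
        arrays(np.float64, 129, elements=st.floats(min_value=0, max_value=1e6)),
    )
    @settings(deadline=None, max_examples=100)
    def test_constraints_always_hold(self, power):
        freqs = np.linspace(0.0, 64.0, 129)
        s = Spectrum(freqs=freqs, power=power)
        try:
            w = identify_weights(s)
        except ValueError:
            return  # all-zero energy in the three bands: correctly rejected
        arr = w.as_array()
        assert np.all(arr >= 0) and np.all(arr <= 1)
        assert arr.sum() == pytest.approx(1.0, abs=1e-12)


class TestDominantFrequency:
    def test_surrogate_eleven_hz(self):
        from ssvepsim.surrogate import SurrogateSpec, generate_surrogate

        ts = generate_surrogate(SurrogateSpec(f0=11.0, seed=1))
        s = compute_psd(ts)
        assert dominant_frequency(s, [10.0, 11.0, 12.0], tol=0.5) == 11.0

    def test_exact_sinusoid(self):
        assert dominant_frequency(compute_psd(_sine(12.0)), [10.0, 11.0, 12.0]) == 12.0

    def test_white_noise_usually_rejected(self):
        # broadband noise rarely puts its argmax within 0.1 Hz of a candidate
        rejections = 0
        for seed in range(20):
            x = np.random.default_rng(seed).normal(0, 1, 4096)
            s = compute_psd(TimeSeries(fs=1024.0, values=x))
            if dominant_frequency(s, [10.0, 11.0, 12.0], tol=0.1) is None:
                rejections += 1
        assert rejections >= 16

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            dominant_frequency(compute_psd(_sine(10.0)), [])


class TestSpectralCentroid:
    def test_single_line(self):
        freqs = np.arange(0.0, 100.0, 1.0)
        power = np.zeros_like(freqs)
        power[42] = 3.0
        assert spectral_centroid(Spectrum(freqs=freqs, power=power)) == pytest.approx(42.0)

    def test_fmax_restriction(self):
        freqs = np.arange(0.0, 100.0, 1.0)
        power = np.zeros_like(freqs)
        power[10] = 1.0
        power[90] = 1.0
        s = Spectrum(freqs=freqs, power=power)
        assert spectral_centroid(s) == pytest.approx(50.0)
        assert spectral_centroid(s, fmax=64.0) == pytest.approx(10.0)


class TestBandTable:
    def test_non_contiguous_rejected(self):
        from ssvepsim.spectral import Band

        with pytest.raises(ValueError):
            BandTable(bands=(Band("a", 0, 4), Band("b", 5, 8)))
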