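import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.signal import periodogram

from stresspipe import wavelet as wv


def band_energy_oracle(signal, fs, low, high):
    """Independent periodogram estimate of energy in [low, high) Hz."""
    freqs, pxx = periodogram(signal, fs=fs)
    mask = (freqs >= low) & (freqs < high)
    return float(np.sum(pxx[mask]))


class TestDecompose:
    def test_zero_signal_all_zero(self):
        decomp = wv.decompose(np.zeros(512))
        assert all(np.all(c == 0) for c in decomp.coeffs.values())
        assert all(np.all(b == 0) for b in decomp.band_signals.values())

    def test_four_details_one_approximation(self):
        decomp = wv.decompose(np.random.default_rng(0).normal(size=512))
        assert sorted(decomp.coeffs) == ["A4", "D1", "D2", "D3", "D4"]

    def test_10hz_tone_concentrates_in_alpha(self):
        t = np.arange(512) / 128.0
        decomp = wv.decompose(np.sin(2 * np.pi * 10.0 * t), fs=128.0)
        energies = {b: float(s @ s) for b, s in decomp.band_signals.items()}
        assert energies["Alpha"] / sum(energies.values()) >= 0.70

    def test_band_signal_lengths_match_input(self):
        x = np.random.default_rng(1).normal(size=1000)
        decomp = wv.decompose(x)
        assert all(s.size == 1000 for s in decomp.band_signals.values())

    def test_nominal_ranges_dyadic_at_128hz(self):
        decomp = wv.decompose(np.zeros(256), fs=128.0)
        assert decomp.nominal_ranges == {
            "Delta": (0.0, 4.0),
            "Theta": (4.0, 8.0),
            "Alpha": (8.0, 16.0),
            "Beta": (16.0, 32.0),
            "Gamma": (32.0, 64.0),
        }

    def test_too_short_signal_raises(self):
        with pytest.raises(wv.SignalTooShortError):
            wv.decompose(np.ones(4))

    def test_non_finite_raises(self):
        x = np.ones(256)
        x[3] = np.nan
        with pytest.raises(wv.NonFiniteSignalError):
            wv.decompose(x)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            wv.WaveletConfig(q=0.0)
        with pytest.raises(ValueError):
            wv.WaveletConfig(levels=0)
        with pytest.raises(ValueError):
            wv.WaveletConfig(wavelet="sym9")


class TestReconstruct:
    @pytest.mark.parametrize("n", [129, 512, 1000])
    def test_perfect_reconstruction(self, n, rng):
        x = rng.normal(size=n)
        decomp = wv.decompose(x)
        assert np.max(np.abs(wv.reconstruct(decomp) - x)) < 1e-8

    @pytest.mark.parametrize("n", [129, 1000, 4096])
    def test_energy_conservation(self, n, rng):
        # circular boundary handling with zero-padding keeps the transform
        # orthogonal at every length, so the 1e-6 bound holds even for odd n
        x = rng.normal(size=n)
        decomp = wv.decompose(x)
        ratio = sum(float(c @ c) for c in decomp.coeffs.values()) / float(x @ x)
        assert abs(ratio - 1.0) < 1e-6

    def test_band_additivity(self, rng):
        x = rng.normal(size=512)
        decomp = wv.decompose(x)
        total = sum(decomp.band_signals.values())
        assert np.max(np.abs(total - wv.reconstruct(decomp))) < 1e-8

    def test_1hz_survives_details_zeroing(self):
        t = np.arange(512) / 128.0
        x = np.sin(2 * np.pi * 1.0 * t)
        decomp = wv.decompose(x, fs=128.0)
        for name in decomp.detail_names():
            decomp.coeffs[name] = np.zeros_like(decomp.coeffs[name])
        approx_only = wv.reconstruct(decomp)
        assert float(approx_only @ approx_only) >= 0.95 * float(x @ x)
        # the retained energy sits in the A4 (0-4 Hz) range per the oracle
        assert band_energy_oracle(approx_only, 128.0, 0.0, 4.0) >= 0.95 * band_energy_oracle(
            x, 128.0, 0.0, 64.0
        )

    def test_all_zero_coeffs_give_zero_series(self):
        decomp = wv.decompose(np.random.default_rng(3).normal(size=256))
        for name in decomp.coeffs:
            decomp.coeffs[name] = np.zeros_like(decomp.coeffs[name])
        assert np.all(wv.reconstruct(decomp) == 0)

    def test_missing_coeffs_raise(self):
        decomp = wv.decompose(np.zeros(256))
        del decomp.coeffs["D2"]
        with pytest.raises(ValueError, match="D2"):
            wv.reconstruct(decomp)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(min_value=130, max_value=900), st.integers(min_value=0, max_value=2**31))
    def test_perfect_reconstruction_property(self, n, seed):
        x = np.random.default_rng(seed).normal(size=n)
        assert np.max(np.abs(wv.reconstruct(wv.decompose(x)) - x)) < 1e-8


class TestSigma:
    def test_closed_form(self):
        decomp = wv.decompose(np.zeros(256))
        decomp.coeffs["D1"] = np.array([0.6745, -0.6745, 0.6745, -0.6745])
        assert wv.estimate_sigma(decomp) == pytest.approx(1.0)

    def test_zero_details_zero_sigma(self):
        assert wv.estimate_sigma(wv.decompose(np.zeros(256))) == 0.0

    def test_mad_consistency_standard_normal(self):
        x = np.random.default_rng(99).normal(size=4096)
        assert 0.9 <= wv.estimate_sigma(wv.decompose(x)) <= 1.1

    def test_empty_d1_raises(self):
        decomp = wv.decompose(np.zeros(256))
        decomp.coeffs["D1"] = np.array([])
        with pytest.raises(ValueError):
            wv.estimate_sigma(decomp)


class TestFdrDenoise:
    def test_zero_details_unchanged(self):
        decomp = wv.decompose(np.zeros(512))
        out = wv.fdr_denoise(decomp, q=0.05, sigma=1.0)
        assert all(np.array_equal(out.coeffs[k], decomp.coeffs[k]) for k in decomp.coeffs)

    def test_zero_sigma_identity(self, rng):
        x = rng.normal(size=512)
        decomp = wv.decompose(x)
        out = wv.fdr_denoise(decomp, q=0.05, sigma=0.0)
        assert all(np.array_equal(out.coeffs[k], decomp.coeffs[k]) for k in decomp.coeffs)

    def test_sparse_spikes_mse_reduced(self):
        r = np.random.default_rng(42)
        n = 1024
        clean = np.zeros(n)
        clean[r.choice(n, size=10, replace=False)] = 10.0
        noisy = clean + r.normal(size=n)
        denoised = wv.reconstruct(wv.fdr_denoise(wv.decompose(noisy), q=0.05))
        assert np.mean((denoised - clean) ** 2) < np.mean((noisy - clean) ** 2)

    def test_tiny_q_on_pure_noise_keeps_approximation_only(self):
        x = np.random.default_rng(5).normal(size=1024)
        decomp = wv.decompose(x)
        out = wv.fdr_denoise(decomp, q=1e-12)
        for name in out.detail_names():
            assert np.all(out.coeffs[name] == 0)
        isolated = wv.decompose(np.zeros(1024))
        isolated.coeffs["A4"] = decomp.coeffs["A4"]
        assert np.allclose(wv.reconstruct(out), wv.reconstruct(isolated), atol=1e-10)

    def test_approximation_untouched(self, rng):
        decomp = wv.decompose(rng.normal(size=512))
        out = wv.fdr_denoise(decomp, q=0.05)
        assert np.array_equal(out.coeffs["A4"], decomp.coeffs["A4"])

    def test_hard_rule_keeps_survivors_verbatim(self, rng):
        decomp = wv.decompose(rng.normal(size=512) * 5)
        out = wv.fdr_denoise(decomp, q=0.2, sigma=0.1)
        for name in out.detail_names():
            kept = out.coeffs[name] != 0
            assert np.array_equal(out.coeffs[name][kept], decomp.coeffs[name][kept])

    @pytest.mark.parametrize("q_pair", [(0.01, 0.05), (0.05, 0.2), (1e-4, 0.5)])
    def test_bh_monotone_in_q(self, q_pair, rng):
        q_low, q_high = q_pair
        x = rng.normal(size=1024)
        x[::50] += 4.0
        decomp = wv.decompose(x)
        sigma = wv.estimate_sigma(decomp)
        low = wv.fdr_denoise(decomp, q=q_low, sigma=sigma)
        high = wv.fdr_denoise(decomp, q=q_high, sigma=sigma)
        for name in decomp.detail_names():
            kept_low = low.coeffs[name] != 0
            kept_high = high.coeffs[name] != 0
            assert np.all(kept_high | ~kept_low), f"{name}: higher q dropped a survivor"

    def test_invalid_q_raises(self):
        decomp = wv.decompose(np.zeros(256))
        with pytest.raises(ValueError):
            wv.fdr_denoise(decomp, q=1.5, sigma=1.0)

    def test_band_signals_refreshed(self, rng):
        x = rng.normal(size=512)
        out = wv.fdr_denoise(wv.decompose(x), q=1e-12)
        for band in ("Theta", "Alpha", "Beta", "Gamma"):
            assert np.all(out.band_signals[band] == 0)
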