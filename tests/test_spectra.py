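"""Spectral estimation against closed forms and constructed signals."""

import numpy as np
import pytest

from statedyn.data import TimeSeriesSet
from statedyn.spectra import (
    aec,
    coherence_from_cpsd,
    glm_mode_spectra,
    multitaper_state_spectra,
    nnmf_bands,
    power_map,
    static_spectra,
)

FS = 250.0


def _ts(x, fs=FS):
    if x.ndim == 1:
        x = x[:, None]
    return TimeSeriesSet([x], sampling_frequency=fs)


def _ar1(T, phi, rng, sigma=1.0):
    x = np.empty(T)
    x[0] = rng.normal() * sigma / np.sqrt(1 - phi**2)
    eps = rng.normal(size=T) * sigma
    for t in range(1, T):
        x[t] = phi * x[t - 1] + eps[t]
    return x


class TestMultitaperPSD:
    def test_white_noise_flat(self, rng):
        se = static_spectra(_ts(rng.normal(size=100_000)))
        freqs, psd = se.frequencies, se.psd[0, 0, 0]
        sel = (freqs > 1) & (freqs < 120)
        n = psd[sel].size // 10 * 10
        binned = psd[sel][:n].reshape(-1, 10).mean(axis=1)
        assert binned.max() / binned.min() < 1.5

    def test_ar1_matches_closed_form(self, rng):
        # 4 s windows: +-1 Hz resolution bandwidth, needed because the
        # AR(1) spectrum changes quickly below ~4 Hz
        phi = 0.9
        x = _ar1(250_000, phi, rng)
        se = static_spectra(_ts(x), window_length=4.0)
        freqs, psd = se.frequencies, se.psd[0, 0, 0]
        omega = 2 * np.pi * freqs / FS
        closed = (2.0 / FS) / np.abs(1 - phi * np.exp(-1j * omega)) ** 2
        sel = (freqs >= 1) & (freqs <= 40)
        rel = np.abs(psd[sel] - closed[sel]) / closed[sel]
        assert rel.max() < 0.10

    def test_parseval(self, rng):
        x = _ar1(100_000, 0.8, rng)
        se = static_spectra(_ts(x))
        df = se.frequencies[1] - se.frequencies[0]
        band_power = se.psd[0, 0, 0, 1:].sum() * df
        assert band_power == pytest.approx(x.var(), rel=0.05)

    def test_state_specific_oscillation_isolated(self, rng):
        # state 1 adds a 20 Hz sinusoid; state 0 is pure noise
        T = 100_000
        t = np.arange(T) / FS
        state = (np.arange(T) // 2500) % 2  # 10 s blocks
        x = rng.normal(size=T) + np.where(state == 1, np.sin(2 * np.pi * 20 * t), 0.0)
        gamma = np.column_stack([state == 0, state == 1]).astype(float)
        se = multitaper_state_spectra(_ts(x), [gamma])
        freqs = se.frequencies
        psd0, psd1 = se.psd[0, 0, 0], se.psd[0, 1, 0]
        peak1 = freqs[np.argmax(psd1)]
        assert abs(peak1 - 20.0) <= freqs[1] - freqs[0]
        band = (freqs > 18) & (freqs < 22)
        out = ((freqs > 1) & (freqs < 15)) | ((freqs > 25) & (freqs < 40))
        prominence1 = psd1[band].max() / psd1[out].mean()
        prominence0 = psd0[band].max() / psd0[out].mean()
        assert prominence1 > 5 * prominence0

    def test_low_occupancy_state_flagged_missing(self, rng):
        gamma = np.zeros((5000, 2))
        gamma[:, 0] = 1.0
        se = multitaper_state_spectra(_ts(rng.normal(size=5000)), [gamma])
        assert se.missing[0, 1]
        assert np.isnan(se.psd[0, 1]).all()

    def test_occupancy_weighted_state_psds_average_to_static(self, rng):
        T = 100_000
        state = (np.arange(T) // 5000) % 2
        x = rng.normal(size=T) * np.where(state == 1, 2.0, 1.0)
        gamma = np.column_stack([state == 0, state == 1]).astype(float)
        se = multitaper_state_spectra(_ts(x), [gamma])
        st = static_spectra(_ts(x))
        fo = gamma.mean(axis=0)
        mixed = fo[0] * se.psd[0, 0, 0] + fo[1] * se.psd[0, 1, 0]
        sel = (se.frequencies > 1) & (se.frequencies < 100)
        rel = np.abs(mixed[sel] - st.psd[0, 0, 0][sel]) / st.psd[0, 0, 0][sel]
        assert np.median(rel) < 0.1


class TestCoherence:
    def test_identical_channels_unit_coherence(self, rng):
        x = rng.normal(size=100_000)
        se = static_spectra(_ts(np.column_stack([x, x])))
        coh = coherence_from_cpsd(se)
        sel = se.frequencies > 1
        assert np.nanmin(coh[0, 0, 0, 1, sel]) > 1 - 1e-10

    def test_independent_channels_low_coherence(self, rng):
        se = static_spectra(_ts(rng.normal(size=(100_000, 2))))
        coh = coherence_from_cpsd(se)
        sel = se.frequencies > 1
        assert np.nanmean(coh[0, 0, 0, 1, sel]) < 0.1

    def test_shared_sinusoid_peak_coherence(self, rng):
        T = 100_000
        t = np.arange(T) / FS
        shared = np.sin(2 * np.pi * 10 * t)
        x = np.column_stack(
            [shared + rng.normal(size=T), shared + rng.normal(size=T)]
        )
        se = static_spectra(_ts(x))
        coh = coherence_from_cpsd(se)[0, 0, 0, 1]
        freqs = se.frequencies
        at_peak = coh[np.argmin(np.abs(freqs - 10))]
        away = coh[(freqs > 20) & (freqs < 40)].mean()
        assert at_peak > 0.9
        assert away < 0.2

    def test_coherence_bounded_and_symmetric(self, rng):
        se = static_spectra(_ts(rng.normal(size=(20_000, 3))))
        coh = coherence_from_cpsd(se)
        finite = coh[np.isfinite(coh)]
        assert (finite >= 0).all() and (finite <= 1).all()
        assert np.allclose(coh[0, 0], np.swapaxes(coh[0, 0], 0, 1), atol=1e-10,
                           equal_nan=True)


class TestGLMModeSpectra:
    def test_block_design_recovers_mode_oscillation(self, rng):
        # mode 1 active in alternating blocks carrying a 15 Hz sinusoid
        T = 100_000
        t = np.arange(T) / FS
        block = (np.arange(T) // 2500) % 2
        x = rng.normal(size=T) + np.where(block == 1, np.sin(2 * np.pi * 15 * t), 0)
        alpha = np.column_stack([1 - block, block]).astype(float)
        se = glm_mode_spectra(_ts(x), [alpha])
        freqs = se.frequencies
        psd1 = se.psd[0, 1, 0]
        assert abs(freqs[np.argmax(psd1)] - 15.0) <= freqs[1] - freqs[0]

    def test_constant_alpha_returns_mean_spectrum(self, rng):
        x = rng.normal(size=20_000)
        alpha = np.column_stack([np.ones(20_000)])
        with pytest.warns(UserWarning, match="degenerate"):
            se = glm_mode_spectra(_ts(x), [alpha])
        st = static_spectra(_ts(x))
        sel = st.frequencies > 1
        rel = np.abs(se.psd[0, 0, 0, sel] - st.psd[0, 0, 0, sel])
        assert np.median(rel / st.psd[0, 0, 0, sel]) < 0.15

    def test_shuffled_alpha_coefficients_near_zero(self, rng):
        T = 50_000
        t = np.arange(T) / FS
        block = (np.arange(T) // 2500) % 2
        x = rng.normal(size=T) + np.where(block == 1, np.sin(2 * np.pi * 15 * t), 0)
        alpha_true = np.column_stack([1 - block, block]).astype(float)
        perm = rng.permutation(T)
        se_true = glm_mode_spectra(_ts(x), [alpha_true])
        se_null = glm_mode_spectra(_ts(x), [alpha_true[perm]])
        # effect spectrum = mode - mean across modes; at the 15 Hz bin the
        # shuffled design must carry almost none of the true effect
        eff_true = np.abs(se_true.psd[0, 1, 0] - se_true.psd[0].mean(axis=0)[0])
        eff_null = np.abs(se_null.psd[0, 1, 0] - se_null.psd[0].mean(axis=0)[0])
        peak = np.argmin(np.abs(se_true.frequencies - 15.0))
        assert eff_true[peak] > 5 * eff_null[peak]


class TestNNMFBands:
    def test_recovers_non_overlapping_band_templates(self, rng):
        freqs = np.linspace(0, 50, 101)
        lowband = np.exp(-0.5 * ((freqs - 10) / 3) ** 2)
        highband = np.exp(-0.5 * ((freqs - 35) / 3) ** 2)
        loadings = rng.random((200, 2))
        X = loadings @ np.stack([lowband, highband])
        comps, W = nnmf_bands(X, 2, seed=0)
        assert np.corrcoef(comps[0], lowband)[0, 1] > 0.95
        assert np.corrcoef(comps[1], highband)[0, 1] > 0.95
        # ordered low band first
        assert comps[0].argmax() < comps[1].argmax()

    def test_single_component_matches_mean_shape(self, rng):
        freqs = np.linspace(0, 50, 101)
        template = np.exp(-0.5 * ((freqs - 20) / 5) ** 2)
        X = rng.random((50, 1)) @ template[None]
        comps, _ = nnmf_bands(X, 1, seed=0)
        assert np.corrcoef(comps[0], X.mean(axis=0))[0, 1] > 0.99

    def test_zero_rows_tolerated(self, rng):
        X = rng.random((20, 30))
        X[::3] = 0.0
        comps, W = nnmf_bands(X, 2, seed=0)
        assert (W[::3] < 1e-8).all() or np.allclose(W[::3], 0, atol=1e-6)


class TestPowerMap:
    def test_flat_psd_rectangle_integral(self):
        freqs = np.linspace(0, 125, 251)
        psd = np.full((1, 1, 1, 251), 3.0)
        from statedyn.spectra import SpectralEstimate

        se = SpectralEstimate(frequencies=freqs, psd=psd)
        p = power_map(se, band=(10, 20))
        width = freqs[(freqs >= 10) & (freqs <= 20)].size * (freqs[1] - freqs[0])
        assert p[0, 0, 0] == pytest.approx(3.0 * width)

    def test_relative_map_of_identical_states_is_zero(self, rng):
        psd = np.tile(rng.random(64), (1, 3, 2, 1))
        from statedyn.spectra import SpectralEstimate

        se = SpectralEstimate(frequencies=np.linspace(0, 40, 64), psd=psd)
        p = power_map(se, band=(5, 30), relative_to_mean=True)
        assert np.allclose(p, 0.0, atol=1e-12)

    def test_sinusoid_band_power(self, rng):
        # a unit sinusoid has total power 1/2 concentrated at its frequency
        T = 100_000
        t = np.arange(T) / FS
        x = np.column_stack(
            [np.sin(2 * np.pi * 20 * t) + 0.1 * rng.normal(size=T),
             0.1 * rng.normal(size=T)]
        )
        se = static_spectra(_ts(x))
        p = power_map(se, band=(15, 25))
        assert p[0, 0, 0] == pytest.approx(0.5, rel=0.1)
        assert p[0, 0, 1] < 0.05


class TestAEC:
    def test_duplicated_channel(self, rng):
        x = rng.normal(size=100_000)
        nets = aec(_ts(np.column_stack([x, x])), band=(8, 12))
        assert nets[0, 0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_independent_channels_near_zero(self, rng):
        nets = aec(_ts(rng.normal(size=(100_000, 2))), band=(8, 12))
        assert abs(nets[0, 0, 1]) < 0.05

    def test_common_amplitude_modulation(self, rng):
        T = 100_000
        t = np.arange(T) / FS
        envelope = 1.0 + 0.9 * np.sin(2 * np.pi * 0.2 * t)
        x = np.column_stack(
            [envelope * np.sin(2 * np.pi * 10 * t + rng.uniform(0, 2 * np.pi)),
             envelope * np.sin(2 * np.pi * 10.7 * t + rng.uniform(0, 2 * np.pi))]
        )
        nets = aec(_ts(x), band=(8, 12))
        assert nets[0, 0, 1] > 0.8
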