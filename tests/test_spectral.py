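"""Frequency grid, multitaper PSD, and aperiodic exponent fitting."""

import numpy as np
import pytest

from planeeg import (
    Recording, build_frequency_grid, fit_aperiodic, generate_colored_noise,
    multitaper_psd, AperiodicSpectrumModel,
)
from planeeg.preprocess import PreprocessConfig, preprocess_recording
from planeeg.spectral import n_tapers

from conftest import make_epochs
from table1 import FREQS


class TestFrequencyGrid:
    def test_default_grid_reproduces_published_frequencies(self):
        grid = build_frequency_grid()
        truncated = np.floor(grid.centers * 1000) / 1000
        np.testing.assert_array_equal(truncated, FREQS)

    def test_first_and_last_centers(self):
        grid = build_frequency_grid()
        assert grid.bins[0] == 4
        assert grid.centers[0] == pytest.approx(0.48828125)
        assert grid.bins[-1] == 164
        assert grid.centers[-1] == pytest.approx(20.01953125)

    def test_snapping_against_brute_force_oracle(self):
        grid = build_frequency_grid()
        bw = 500.0 / 4096
        targets = np.logspace(np.log10(0.5), np.log10(20.0), 23)
        # brute force: for each target scan all bins for the closest center
        all_bins = np.arange(1, 2048)
        expected = sorted({
            all_bins[np.argmin(np.abs(all_bins * bw - t))] for t in targets})
        np.testing.assert_array_equal(grid.bins, expected)

    def test_pad_length_and_bin_width(self):
        grid = build_frequency_grid()
        assert grid.pad_length == 4096
        assert grid.bin_width == pytest.approx(0.1220703125)

    def test_extended_grid_collapses_duplicates_with_warning(self):
        with pytest.warns(UserWarning, match="collapsed"):
            grid = build_frequency_grid(0.5, 80.0, 44)
        assert grid.centers.size < 44
        assert np.all(np.diff(grid.bins) > 0)

    def test_fmax_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            build_frequency_grid(0.5, 250.0, 23)


class TestMultitaperPsd:
    def test_default_taper_count_is_11(self):
        assert n_tapers(6.0, 1.0) == 11

    def test_tiny_smoothing_rejected(self):
        with pytest.raises(ValueError):
            n_tapers(6.0, 0.05)

    def test_white_noise_spectrum_is_flat(self, rng):
        data = rng.standard_normal((99, 1, 3000))
        grid = build_frequency_grid()
        freqs, power = multitaper_psd(make_epochs(data), grid)
        slope = np.polyfit(np.log10(freqs), np.log10(power), 1)[0]
        assert abs(slope) < 0.05

    def test_sinusoid_power_concentrated_within_smoothing_band(self):
        center = 26 * 500.0 / 4096  # 3.173 Hz, a grid center
        t = np.arange(3000) / 500.0
        data = np.tile(np.sin(2 * np.pi * center * t), (5, 1, 1))
        grid = build_frequency_grid()
        freqs, power = multitaper_psd(make_epochs(data), grid)
        assert freqs[np.argmax(power)] == pytest.approx(center)
        far = np.abs(freqs - center) > 1.0
        # out-of-band power suppressed by > 20 dB (DPSS sidelobe floor)
        assert power[far].max() < 1e-2 * power.max()

    def test_parseval_white_noise_variance_recovered(self, rng):
        data = rng.standard_normal((30, 1, 3000))
        freqs, psd = multitaper_psd(make_epochs(data))
        integral = np.trapezoid(psd, freqs)
        assert integral == pytest.approx(data.var(), rel=0.1)


class TestAperiodicFit:
    @pytest.mark.parametrize("x", [0.0, 0.7, 2.0, 4.0])
    def test_exact_on_noiseless_power_law(self, x):
        grid = build_frequency_grid()
        power = grid.centers ** (-x)
        fit = fit_aperiodic(grid.centers, power, (0.5, 20.0))
        assert fit.exponent == pytest.approx(x, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_flat_spectrum_gives_zero_exponent(self):
        grid = build_frequency_grid()
        fit = fit_aperiodic(grid.centers, np.full(23, 2.5), (0.5, 20.0))
        assert fit.exponent == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_power_excluded_with_warning(self):
        grid = build_frequency_grid()
        power = grid.centers ** -1.0
        power[5] = 0.0
        with pytest.warns(UserWarning, match="non-positive"):
            # range spanning all 23 snapped centers
            fit = fit_aperiodic(grid.centers, power, (0.4, 20.5))
        assert fit.n_points == 22
        assert fit.exponent == pytest.approx(1.0, abs=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_aperiodic(np.array([1.0, 2.0, 4.0, 8.0]),
                          np.array([1.0, 0.5, 0.0, 0.0]), (0.5, 20.0))

    def test_pipeline_recovers_unit_exponent(self):
        """Synthetic x=1 noise through filters, epoching and the model;
        oracle: independent log-log regression on the multitaper output."""
        x = generate_colored_noise(300_000, 500.0, 1.0, seed=21)
        rec = Recording(data=x, fs=500.0)
        epochs = preprocess_recording(rec, PreprocessConfig())
        assert epochs.n_epochs == 99
        res = AperiodicSpectrumModel(epochs).fit()
        assert res.exponent == pytest.approx(1.0, abs=0.1)
        sel = (res.freqs >= 2.0) & (res.freqs <= 20.0)
        oracle = -np.polyfit(np.log10(res.freqs[sel]),
                             np.log10(res.power[sel]), 1)[0]
        assert res.exponent == pytest.approx(oracle, abs=1e-9)

    @pytest.mark.parametrize("x", [0.5, 1.0, 1.5, 2.7])
    def test_parameter_recovery_across_exponents(self, x):
        """Mean absolute error below 0.1 over seeded replicates (reduced
        replicate count here; the acceptance suite runs 20)."""
        errors = []
        for rep in range(5):
            sig = generate_colored_noise(150_000, 500.0, x, seed=300 + rep)
            epochs = preprocess_recording(Recording(data=sig, fs=500.0))
            res = AperiodicSpectrumModel(epochs).fit()
            errors.append(abs(res.exponent - x))
        assert np.mean(errors) < 0.1

    def test_results_summary_mentions_key_quantities(self, rng):
        data = rng.standard_normal((12, 1, 3000))
        res = AperiodicSpectrumModel(make_epochs(data)).fit()
        text = res.summary()
        assert "exponent" in text and "R^2" in text and "11" in text
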