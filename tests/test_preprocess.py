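"""Conditioning-chain contracts: each stage alone, then the composed pipeline."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import ramantissue as rt
from ramantissue.preprocess import (
    DegenerateSpectrumWarning,
    EmptySpectrumError,
    PreprocessConfig,
    despike_median,
    fit_baseline,
    normalize_minmax,
    preprocess_dataset,
    preprocess_pipeline,
    smooth_savgol,
    subtract_baseline,
    truncate_fingerprint,
)
from ramantissue.simulate import PeakSpec, TissueProfile
from ramantissue.spectra import Spectrum


def spec(intensity, axis=None):
    intensity = np.asarray(intensity, dtype=float)
    if axis is None:
        axis = np.arange(1.0, intensity.size + 1.0)
    return Spectrum(axis, intensity)


class TestFitBaseline:
    def test_exact_polynomial_reproduced(self, axis):
        t = (axis - axis[0]) / (axis[-1] - axis[0])
        y = 2.0 + 0.5 * t - 1.5 * t**2 + t**3 - 0.3 * t**4 + 0.1 * t**5
        s = Spectrum(axis, y)
        for method in ("modpoly", "ls"):
            b = fit_baseline(s, 5, method=method)
            assert np.max(np.abs(b - y)) < 1e-6 * np.max(np.abs(y))

    def test_constant_order_zero(self):
        s = spec(np.full(50, 3.0))
        assert np.allclose(fit_baseline(s, 0), 3.0)

    def test_peak_recovered_after_subtraction(self, axis):
        """Polynomial background + one Lorentzian: after baseline removal
        the recovered peak amplitude is within 5% of the truth."""
        t = (axis - axis[0]) / (axis[-1] - axis[0])
        background = 3.0 + 1.2 * t - 0.8 * t**2 + 0.4 * t**3
        peak = PeakSpec(center=1100.0, width=8.0, amplitude=1.0)
        y = background + peak.evaluate(axis)
        s = Spectrum(axis, y)
        corrected = subtract_baseline(s, fit_baseline(s, 5))
        recovered = corrected.intensity[np.argmin(np.abs(axis - 1100.0))]
        assert abs(recovered - 1.0) < 0.05

    def test_too_short_spectrum_rejected(self):
        with pytest.raises(ValueError):
            fit_baseline(spec([1.0, 2.0, 3.0]), 5)


class TestSubtractBaseline:
    def test_self_subtraction_zeroes(self, axis):
        y = np.sin(axis / 50.0) + 2.0
        s = Spectrum(axis, y)
        assert np.all(subtract_baseline(s, y).intensity == 0.0)

    def test_zero_baseline_identity(self):
        s = spec([1.0, 5.0, 2.0])
        out = subtract_baseline(s, np.zeros(3))
        assert np.array_equal(out.intensity, s.intensity)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            subtract_baseline(spec([1.0, 2.0]), np.zeros(3))

    def test_generator_baseline_mostly_removed(self, axis):
        """On a generated spectrum with a known polynomial background, the
        residual background power after correction is < 5% of the original."""
        prof = TissueProfile(
            tissue_class="FAT",
            peaks=rt.default_profiles()["FAT"].peaks,
            noise_sigma=0.0, spike_prob=0.0, peak_jitter=0.0, amplitude_cv=0.0,
        )
        rng = np.random.default_rng(8)
        ls = rt.generate_spectrum(prof, axis, rng)
        from ramantissue.simulate import template_intensity
        truth_baseline = ls.spectrum.intensity - template_intensity(prof, axis)
        corrected = subtract_baseline(
            ls.spectrum, fit_baseline(ls.spectrum, 5)
        )
        residual = corrected.intensity - template_intensity(prof, axis)
        assert np.sum(residual**2) < 0.05 * np.sum(truth_baseline**2)


class TestDespikeMedian:
    def test_monotone_ramp_unchanged_interior(self):
        out = despike_median(spec([1, 2, 3, 4, 5]), kernel=3)
        assert np.array_equal(out.intensity[1:4], [2, 3, 4])

    def test_single_spike_removed(self):
        y = np.full(21, 2.0)
        y[10] += 100.0
        out = despike_median(spec(y), kernel=3)
        assert out.intensity[10] == 2.0

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            despike_median(spec(np.ones(10)), kernel=4)

    def test_spiked_twin_matches_clean_twin(self, axis, profiles):
        """Paired simulation: despiking a spiked spectrum lands within
        3*noise_sigma of its spike-free twin at the spike channel."""
        base = profiles["FAT"]
        clean_prof = TissueProfile(tissue_class="FAT", peaks=base.peaks,
                                   spike_prob=0.0)
        spiked_prof = TissueProfile(tissue_class="FAT", peaks=base.peaks,
                                    spike_prob=1.0)
        clean = rt.generate_spectrum(clean_prof, axis, np.random.default_rng(99))
        spiked = rt.generate_spectrum(spiked_prof, axis, np.random.default_rng(99))
        spike_channel = int(np.argmax(spiked.spectrum.intensity
                                      - clean.spectrum.intensity))
        out = despike_median(spiked.spectrum, kernel=5)
        err = abs(out.intensity[spike_channel]
                  - clean.spectrum.intensity[spike_channel])
        assert err < 3 * base.noise_sigma


class TestSmoothSavgol:
    @pytest.mark.parametrize("window", [5, 11, 25])
    def test_exact_on_cubic(self, window):
        x = np.linspace(0.0, 1.0, 200)
        y = 1.0 - 2.0 * x + 3.0 * x**2 - 0.5 * x**3
        out = smooth_savgol(Spectrum(x * 1000 + 100, y), window=window, polyorder=3)
        assert np.max(np.abs(out.intensity - y)) < 1e-8 * np.max(np.abs(y))

    def test_constant_unchanged(self):
        out = smooth_savgol(spec(np.full(50, 4.2)), window=11, polyorder=3)
        assert np.allclose(out.intensity, 4.2)

    def test_noise_variance_reduced(self):
        rng = np.random.default_rng(0)
        y = rng.normal(0.0, 1.0, size=1000)
        out = smooth_savgol(spec(y), window=11, polyorder=3)
        assert np.std(out.intensity) < np.std(y)

    def test_window_not_exceeding_order_rejected(self):
        with pytest.raises(ValueError):
            smooth_savgol(spec(np.ones(50)), window=3, polyorder=3)


class TestNormalizeMinmax:
    def test_three_point_example(self):
        out = normalize_minmax(spec([2.0, 4.0, 6.0]))
        assert np.allclose(out.intensity, [0.0, 0.5, 1.0])

    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=40))
    def test_output_range_is_unit(self, values):
        values = np.asarray(values)
        if np.ptp(values) == 0:
            return
        out = normalize_minmax(spec(values))
        assert out.intensity.min() == 0.0
        assert out.intensity.max() == 1.0

    def test_constant_spectrum_zeroed_with_warning(self):
        with pytest.warns(DegenerateSpectrumWarning):
            out = normalize_minmax(spec([5.0, 5.0, 5.0]))
        assert np.all(out.intensity == 0.0)

    def test_idempotent_on_normalized(self):
        out = normalize_minmax(spec([2.0, 4.0, 6.0]))
        again = normalize_minmax(out)
        assert np.allclose(again.intensity, out.intensity)


class TestTruncateFingerprint:
    def test_sample_count_on_coarse_axis(self):
        axis = np.arange(100.0, 3201.0, 2.0)
        s = Spectrum(axis, np.ones_like(axis))
        out = truncate_fingerprint(s, 400.0, 1800.0)
        assert len(out) == (1800 - 400) // 2 + 1 == 701

    def test_idempotent_when_already_inside(self, axis):
        s = Spectrum(axis, np.ones_like(axis))
        out = truncate_fingerprint(s, 400.0, 1800.0)
        assert np.array_equal(out.wavenumbers, axis)

    def test_empty_interval_rejected(self, axis):
        with pytest.raises(EmptySpectrumError):
            truncate_fingerprint(Spectrum(axis, np.ones_like(axis)), 5000.0, 6000.0)

    def test_closed_interval_keeps_endpoints(self):
        axis = np.arange(399.0, 1803.0, 1.0)
        out = truncate_fingerprint(Spectrum(axis, np.ones_like(axis)))
        assert out.wavenumbers[0] == 400.0
        assert out.wavenumbers[-1] == 1800.0


class TestPipeline:
    def test_output_in_unit_range_and_fingerprint(self, profiles):
        from ramantissue.spectra import wide_axis

        ls = rt.generate_spectrum(profiles["FAT"], wide_axis(),
                                  np.random.default_rng(0))
        out = preprocess_pipeline(ls.spectrum)
        assert out.intensity.min() >= 0.0
        assert out.intensity.max() <= 1.0
        assert out.wavenumbers[0] >= 400.0
        assert out.wavenumbers[-1] <= 1800.0

    def test_provenance_records_stage_order(self, axis, profiles):
        ls = rt.generate_spectrum(profiles["MSC"], axis, np.random.default_rng(1))
        out = preprocess_pipeline(ls.spectrum)
        assert [r["stage"] for r in out.provenance] == [
            "baseline", "despike", "smooth", "normalize", "truncate"
        ]

    def test_skip_stage_logged_not_reordered(self, axis, profiles):
        ls = rt.generate_spectrum(profiles["MSC"], axis, np.random.default_rng(1))
        cfg = PreprocessConfig(skip_stages=("despike",))
        out = preprocess_pipeline(ls.spectrum, cfg)
        stages = [(r["stage"], r.get("skipped", False)) for r in out.provenance]
        assert stages[1] == ("despike", True)

    def test_spiked_and_clean_twins_agree(self, axis, profiles):
        base = profiles["FAT"]
        clean_prof = TissueProfile(tissue_class="FAT", peaks=base.peaks,
                                   spike_prob=0.0)
        spiked_prof = TissueProfile(tissue_class="FAT", peaks=base.peaks,
                                    spike_prob=1.0)
        seed = 31
        clean = rt.generate_spectrum(clean_prof, axis, np.random.default_rng(seed))
        spiked = rt.generate_spectrum(spiked_prof, axis, np.random.default_rng(seed))
        a = preprocess_pipeline(clean.spectrum)
        b = preprocess_pipeline(spiked.spectrum)
        assert np.max(np.abs(a.intensity - b.intensity)) < 3 * base.noise_sigma

    def test_single_peak_position_survives_pipeline(self, axis):
        prof = TissueProfile(
            tissue_class="FAT",
            peaks=(PeakSpec(center=1200.0, width=8.0, amplitude=1.0),),
            noise_sigma=0.01, spike_prob=0.0, peak_jitter=0.0, amplitude_cv=0.0,
        )
        ls = rt.generate_spectrum(prof, axis, np.random.default_rng(4))
        out = preprocess_pipeline(ls.spectrum)
        true_idx = int(np.argmin(np.abs(out.wavenumbers - 1200.0)))
        assert abs(int(np.argmax(out.intensity)) - true_idx) <= 1

    def test_never_produces_nonfinite(self, axis, profiles):
        for cls in rt.TISSUE_CLASSES:
            ls = rt.generate_spectrum(profiles[cls], axis, np.random.default_rng(6))
            out = preprocess_pipeline(ls.spectrum)
            assert np.all(np.isfinite(out.intensity))

    def test_batch_path_matches_per_spectrum_path(self, small_dataset):
        """The vectorized dataset chain agrees with the one-spectrum chain."""
        sub = small_dataset.subset(range(0, len(small_dataset), 40))
        batch = preprocess_dataset(sub)
        for i, ls in enumerate(sub.iter_spectra()):
            single = preprocess_pipeline(ls.spectrum)
            assert np.allclose(batch.intensities[i], single.intensity,
                               atol=1e-10)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            PreprocessConfig(median_kernel=4)
        with pytest.raises(ValueError):
            PreprocessConfig(savgol_window=5, savgol_polyorder=5)
        with pytest.raises(ValueError):
            PreprocessConfig(fingerprint_lo=1800.0, fingerprint_hi=400.0)
        with pytest.raises(ValueError):
            PreprocessConfig(skip_stages=("resample",))
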