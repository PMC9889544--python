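import numpy as np
import pytest

from nirsleep.exceptions import (
    DataError,
    DimensionError,
    GroupingError,
    ParameterError,
)
from nirsleep.preprocess import HemoSeries
from nirsleep.spectral import (
    PSDResult,
    compute_psd,
    estimate_frequency_shift,
    find_spectral_peaks,
    group_mean_psd,
    peak_frequency,
    smooth_log_psd,
)

FS = 15.625


def _tone(freq, n=2048, fs=FS, amp=1.0, phase=0.0):
    t = np.arange(n) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)


class TestComputePsd:
    def test_tone_argmax_at_tone_frequency(self):
        p = compute_psd(_tone(2.0), FS, "periodogram")
        assert abs(p.freqs[np.argmax(p.power)] - 2.0) <= p.df

    def test_parseval_for_periodogram(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=4096)
        p = compute_psd(x, FS, "periodogram")
        total = p.power.sum() * p.df
        assert abs(total - x.var()) / x.var() < 0.01

    def test_constant_series_is_dc_only(self):
        p = compute_psd(np.full(256, 5.0), FS, "periodogram")
        assert np.allclose(p.power[1:], 0.0, atol=1e-20)

    def test_power_scales_quadratically(self):
        x = _tone(1.0, 512)
        p1 = compute_psd(x, FS)
        p3 = compute_psd(3.0 * x, FS)
        assert np.allclose(p3.power, 9.0 * p1.power, rtol=1e-9, atol=1e-12)

    def test_rejects_bad_inputs(self):
        with pytest.raises(DataError):
            compute_psd(np.array([1.0, np.nan] * 8), FS)
        with pytest.raises(ParameterError):
            compute_psd(np.ones(4), FS)
        with pytest.raises(ParameterError):
            compute_psd(np.ones(64), FS, method="multitaper")


def _hemo_from(x, sex="female", sid="s"):
    arr = np.asarray(x)[:, None]
    return HemoSeries(sid, sex, FS, arr, -0.3 * arr)


class TestGroupMeanPsd:
    def test_identical_subjects_equal_single_psd(self):
        x = _tone(1.5, 1024)
        cohort = [_hemo_from(x, sid=f"s{i}") for i in range(4)]
        g = group_mean_psd(cohort, "female", "HbO", method="periodogram")
        single = compute_psd(x, FS, "periodogram")
        assert np.allclose(g.power, single.power)

    def test_two_tone_average_has_quarter_power(self):
        # exact Fourier-bin tones; averaging halves each amplitude
        n = 2048
        f1, f2 = 64 * FS / n, 192 * FS / n
        x1, x2 = _tone(f1, n), _tone(f2, n)
        cohort = [_hemo_from(x1, sid="a"), _hemo_from(x2, sid="b")]
        g = group_mean_psd(cohort, "female", "HbO", method="periodogram")
        p1 = compute_psd(x1, FS, "periodogram")
        i1 = int(np.argmin(np.abs(g.freqs - f1)))
        assert np.isclose(g.power[i1], p1.power[i1] / 4.0, rtol=1e-6)

    def test_empty_group_raises(self):
        cohort = [_hemo_from(_tone(1.0))]
        with pytest.raises(GroupingError):
            group_mean_psd(cohort, "male", "HbO")

    def test_average_spectra_mode(self):
        x1, x2 = _tone(1.0, 1024), _tone(3.0, 1024)
        cohort = [_hemo_from(x1, sid="a"), _hemo_from(x2, sid="b")]
        g = group_mean_psd(cohort, "female", "HbO", method="periodogram",
                           mode="average-spectra")
        ref = (compute_psd(x1, FS, "periodogram").power
               + compute_psd(x2, FS, "periodogram").power) / 2
        assert np.allclose(g.power, ref)


class TestSmoothLogPsd:
    def test_window_one_is_pointwise_log(self):
        p = compute_psd(_tone(2.0, 512), FS)
        s = smooth_log_psd(p, 1)
        eps = 1e-20 * p.power.max()
        assert np.allclose(s.power, np.log10(p.power + eps))

    def test_constant_spectrum_preserved(self):
        p = PSDResult(np.linspace(0, 5, 32), np.full(32, 4.0), FS, "periodogram")
        s = smooth_log_psd(p, 5)
        assert np.allclose(s.power, np.log10(4.0 + 1e-20 * 4.0))

    def test_step_spectrum_hand_computed(self):
        power = np.array([1.0, 1.0, 1.0, 100.0, 100.0, 100.0])
        p = PSDResult(np.arange(6.0), power, FS, "periodogram")
        s = smooth_log_psd(p, 3)
        eps = 1e-20 * 100
        lp = np.log10(power + eps)
        # reflective boundaries: [lp1, lp0..lp5, lp4]
        expected = [
            (lp[1] + lp[0] + lp[1]) / 3,
            (lp[0] + lp[1] + lp[2]) / 3,
            (lp[1] + lp[2] + lp[3]) / 3,
            (lp[2] + lp[3] + lp[4]) / 3,
            (lp[3] + lp[4] + lp[5]) / 3,
            (lp[4] + lp[5] + lp[4]) / 3,
        ]
        assert np.allclose(s.power, expected)

    def test_even_window_rejected(self):
        p = compute_psd(_tone(2.0, 512), FS)
        with pytest.raises(ParameterError):
            smooth_log_psd(p, 4)


class TestPeaks:
    def test_two_tones_ranked_by_height(self):
        x = _tone(2.0, 4096) + 0.5 * _tone(4.0, 4096)
        p = compute_psd(x, FS, "periodogram")
        pk = find_spectral_peaks(p, (1.0, 5.0), n_peaks=2)
        assert abs(pk[0] - 2.0) <= 2 * p.df
        assert abs(pk[1] - 4.0) <= 2 * p.df

    def test_white_noise_returns_available_maxima(self):
        rng = np.random.default_rng(3)
        p = compute_psd(rng.normal(size=256), FS, "periodogram")
        pk = find_spectral_peaks(p, (1.0, 2.0), n_peaks=10**6)
        assert 0 < len(pk) < 10**6

    def test_empty_band_rejected(self):
        p = compute_psd(_tone(2.0, 512), FS)
        with pytest.raises(ParameterError):
            find_spectral_peaks(p, (3.0, 2.0))

    def test_peak_frequency_on_pure_tone(self):
        p = compute_psd(_tone(2.0, 4096), FS, "periodogram")
        assert abs(peak_frequency(p, (1, 3)) - 2.0) < 2 * p.df


class TestFrequencyShift:
    def _bump(self, center, width=0.15):
        f = np.arange(0, FS / 2, 0.0167)
        power = 1e-3 + np.exp(-0.5 * ((f - center) / width) ** 2)
        return PSDResult(f, power, FS, "synthetic")

    def test_identical_curves_zero_shift(self):
        p = self._bump(2.0)
        for method in ("peak-centroid", "xcorr"):
            assert abs(estimate_frequency_shift(p, p, (1, 3), method=method)) < 1e-9

    def test_two_bin_displacement_recovered(self):
        pa = self._bump(2.0)
        pb = self._bump(2.0 + 2 * 0.0167)
        for method in ("peak-centroid", "xcorr"):
            sh = estimate_frequency_shift(pa, pb, (1, 3), method=method)
            assert abs(sh - 2 * 0.0167) <= 0.0167 / 2

    def test_antisymmetry(self):
        pa, pb = self._bump(2.0), self._bump(2.1)
        for method in ("peak-centroid", "xcorr"):
            ab = estimate_frequency_shift(pa, pb, (1, 3), method=method)
            ba = estimate_frequency_shift(pb, pa, (1, 3), method=method)
            assert np.isclose(ab, -ba, atol=5e-3)

    def test_grid_mismatch_rejected(self):
        pa = self._bump(2.0)
        pb = PSDResult(pa.freqs[:-1], pa.power[:-1], FS, "synthetic")
        with pytest.raises(DimensionError):
            estimate_frequency_shift(pa, pb, (1, 3))
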