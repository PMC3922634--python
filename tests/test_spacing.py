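"""Autocorrelation spacing estimator: oracles, identities, peak logic."""

import numpy as np
import pytest

from gfb3d.io_formats import ImageVolume, LabelVolume
from gfb3d.spacing import (SpacingParams, SpacingProfile, autocorrelation_map,
                           calibrate_threshold, detect_peaks, estimate_spacing,
                           radial_profile, sample_rois, _taper_window)


def direct_autocorrelation(window: np.ndarray, taper_fraction: float = 0.1) -> np.ndarray:
    """O(n^4) shift-and-multiply autocorrelation oracle (zero-padded, normalised)."""
    n = window.shape[0]
    t = _taper_window(n, taper_fraction)
    g = (window - window.mean()) * np.outer(t, t)
    npad = 2 * n
    out = np.zeros((npad, npad))
    for sy in range(-n + 1, n):
        for sx in range(-n + 1, n):
            a = g[max(0, sy):n + min(0, sy), max(0, sx):n + min(0, sx)]
            b = g[max(0, -sy):n + min(0, -sy), max(0, -sx):n + min(0, -sx)]
            out[npad // 2 + sy, npad // 2 + sx] = (a * b).sum()
    return out / out[npad // 2, npad // 2]


class TestAutocorrelation:
    def test_fft_equals_direct_sum_oracle(self, rng):
        win = rng.normal(size=(16, 16))
        np.testing.assert_allclose(autocorrelation_map(win),
                                   direct_autocorrelation(win), atol=1e-10)

    def test_origin_is_one_and_centrosymmetric(self, rng):
        acf = autocorrelation_map(rng.normal(size=(32, 32)))
        n = acf.shape[0]
        assert acf[n // 2, n // 2] == pytest.approx(1.0)
        flipped = np.roll(acf[::-1, ::-1], (1, 1), axis=(0, 1))
        np.testing.assert_allclose(acf, flipped, atol=1e-10)

    def test_constant_window_raises(self):
        with pytest.raises(ValueError, match="zero variance"):
            autocorrelation_map(np.full((16, 16), 3.0))

    def test_cosine_grating_peak_at_period(self, rng):
        px, n, period = 1.5, 100, 20.0
        x = (np.arange(n) + 0.5) * px
        img = 100 + 50 * np.cos(2 * np.pi * x / period)[None, :].repeat(n, axis=0)
        img += rng.normal(0, 1, size=img.shape)
        prof = radial_profile(autocorrelation_map(img), (0.0, 1.0), 15.0, px,
                              max_radius_px=50)
        peaks = detect_peaks(prof, threshold=0.0)
        assert peaks[0] == pytest.approx(period, abs=px)


class TestRadialProfile:
    def test_isotropic_map_direction_independent(self, rng):
        from scipy import ndimage

        img = ndimage.gaussian_filter(rng.normal(size=(64, 64)), 2.0)
        acf = autocorrelation_map(img)
        p1 = radial_profile(acf, (0.0, 1.0), 90.0, 1.0)
        p2 = radial_profile(acf, (1.0, 0.0), 90.0, 1.0)
        np.testing.assert_allclose(p1.correlation, p2.correlation, atol=1e-12)

    def test_sector_90_is_full_rotational_average(self, rng):
        acf = autocorrelation_map(rng.normal(size=(32, 32)))
        full = radial_profile(acf, (0.0, 1.0), 90.0, 1.0)
        n = acf.shape[0]
        yy = np.arange(n)[:, None] - n // 2
        xx = np.arange(n)[None, :] - n // 2
        rbin = np.round(np.hypot(yy, xx)).astype(int)
        for k in (3, 7, 11):
            assert full.correlation[full.radii_nm == k] == pytest.approx(
                acf[rbin == k].mean())

    def test_grating_profile_oscillates_along_grating_axis(self):
        px, n = 1.0, 64
        img = np.cos(2 * np.pi * np.arange(n) / 16.0)[None, :].repeat(n, axis=0)
        prof = radial_profile(autocorrelation_map(img + 2.0), (0.0, 1.0), 10.0, px)
        peaks = detect_peaks(prof, 0.0)
        assert peaks[0] == pytest.approx(16.0, abs=1.0)

    def test_origin_bin_is_profile_maximum(self, rng):
        prof = radial_profile(autocorrelation_map(rng.normal(size=(32, 32))),
                              (0.0, 1.0), 15.0, 1.0)
        assert prof.correlation[0] == prof.correlation.max() == pytest.approx(1.0)


class TestDetectPeaks:
    def _profile(self, values, power=1.0):
        return SpacingProfile(np.arange(len(values), dtype=float), np.asarray(values),
                              second_differential=np.r_[
                                  0.0, np.diff(values, 2), 0.0],
                              origin_power=power)

    def test_monotone_decay_has_no_peaks(self):
        prof = self._profile(np.exp(-np.arange(30) / 5.0))
        assert len(detect_peaks(prof, 0.0, smooth_bins=1)) == 0

    def test_two_peaks_predominant_is_smallest(self):
        r = np.arange(60, dtype=float)
        corr = np.exp(-r / 4) + 0.5 * np.exp(-((r - 20) ** 2) / 8) \
            + 0.3 * np.exp(-((r - 40) ** 2) / 8)
        prof = self._profile(corr)
        peaks = detect_peaks(prof, 1e-4, smooth_bins=1)
        assert len(peaks) >= 2
        assert peaks[0] == pytest.approx(20.0, abs=1.0)
        assert peaks[0] == min(peaks)

    def test_infinite_threshold_empty(self):
        r = np.arange(60, dtype=float)
        corr = np.exp(-r / 4) + 0.5 * np.exp(-((r - 20) ** 2) / 8)
        assert len(detect_peaks(self._profile(corr), np.inf)) == 0

    def test_min_radius_excludes_small_lags(self):
        r = np.arange(60, dtype=float)
        corr = np.exp(-r / 4) + 0.5 * np.exp(-((r - 6) ** 2) / 2) \
            + 0.4 * np.exp(-((r - 20) ** 2) / 8)
        peaks = detect_peaks(self._profile(corr), 1e-4, smooth_bins=1, min_radius_nm=10.0)
        assert peaks[0] == pytest.approx(20.0, abs=1.0)


class TestCalibration:
    def test_zero_noise_blanks_give_zero_threshold(self):
        blanks = [np.full((32, 32), 50.0) for _ in range(25)]
        assert calibrate_threshold(blanks) == 0.0

    def test_reproducible_bit_exactly(self, rng):
        blanks = [rng.normal(50, 5, size=(32, 32)) for _ in range(25)]
        assert calibrate_threshold(blanks) == calibrate_threshold(blanks)

    def test_too_few_windows(self, rng):
        with pytest.raises(ValueError, match="20"):
            calibrate_threshold([rng.normal(size=(16, 16))] * 5)

    def test_false_peak_rate_bounded_on_held_out_blanks(self, rng):
        """At the 95th-percentile threshold, few held-out iid blanks show peaks."""
        make = lambda: rng.normal(50, 5, size=(64, 64))
        calib = [make() for _ in range(100)]
        held = [make() for _ in range(100)]
        thr = calibrate_threshold(calib, min_radius_nm=8.0)
        fp = 0
        for win in held:
            prof = radial_profile(autocorrelation_map(win), (0.0, 1.0), 15.0, 1.0,
                                  origin_power=float(np.var(win)))
            if len(detect_peaks(prof, thr, min_radius_nm=8.0)):
                fp += 1
        assert fp <= 8  # ~5% by construction, with binomial slack at n=100


class TestSampleRois:
    def _slab(self, nz=4, ny=24, nx=24, vox=25.0):
        vol = ImageVolume(np.zeros((nz, ny, nx)), (vox, vox, vox))
        mask = np.ones((nz, ny, nx), dtype=bool)
        return vol, mask

    def test_empty_mask_gives_empty_sequence(self):
        vol, mask = self._slab()
        with pytest.warns(UserWarning):
            assert sample_rois(vol, np.zeros_like(mask), 150.0, 150.0) == []

    def test_grid_count_for_full_slab(self):
        # 600 x 600 nm slices at 150 nm windows / 150 nm stride: 16 per slice
        vol, mask = self._slab()
        rois = sample_rois(vol, mask, 150.0, 150.0)
        assert len(rois) == 16 * 4

    def test_window_coordinates_identical_across_slices(self):
        vol, mask = self._slab()
        rois = sample_rois(vol, mask, 150.0, 150.0)
        per_slice = {}
        for roi in rois:
            per_slice.setdefault(roi.slice_index, []).append(roi.origin_nm)
        origins = list(per_slice.values())
        assert all(o == origins[0] for o in origins)

    def test_qualification_fraction(self):
        vol, mask = self._slab()
        mask[:, :, :12] = False  # half of each window row masked out
        rois = sample_rois(vol, mask, 150.0, 150.0, min_mask_fraction=0.8)
        assert {roi.origin_nm[1] for roi in rois} == {300.0, 450.0}


def test_estimate_spacing_on_blank_volume_with_empty_mask(rng):
    vol = ImageVolume(rng.normal(50, 5, size=(4, 120, 120)), (1.5, 1.5, 1.5))
    empty = np.zeros(vol.shape, dtype=bool)
    blanks = [rng.normal(50, 5, size=(100, 100)) for _ in range(25)]
    with pytest.warns(UserWarning):
        res = estimate_spacing(vol, empty, blanks, SpacingParams())
    assert res.n_areas == 0
    assert len(res.predominant_nm) == 0
    assert np.isnan(res.mean_predominant_spacing_nm)
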