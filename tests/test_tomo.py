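"""Tilt-series simulation and weighted back-projection."""

import math

import numpy as np
import pytest

from gfb3d.io_formats import ImageVolume
from gfb3d.tomo import (AcquisitionSpec, TiltSeries, combine_dual_axis,
                        corrected_z_resolution, exposure_time, project,
                        read_tilt_series, simulate_tilt_series, wbp_reconstruct,
                        write_tilt_series)


class TestExposureModel:
    def test_anchored_at_printed_exposures(self):
        spec = AcquisitionSpec()
        assert exposure_time(0.0, spec) == pytest.approx(2.0)
        assert exposure_time(60.0, spec) == pytest.approx(3.2)
        assert exposure_time(-60.0, spec) == pytest.approx(3.2)

    def test_secant_form_at_45_degrees(self):
        # t(45) = 2.0 + 1.2 (sqrt(2) - 1)
        assert exposure_time(45.0, AcquisitionSpec()) == pytest.approx(
            2.0 + 1.2 * (math.sqrt(2) - 1.0))

    def test_monotone_and_symmetric(self):
        spec = AcquisitionSpec()
        ts = [exposure_time(t, spec) for t in range(0, 61, 5)]
        assert all(b > a for a, b in zip(ts, ts[1:]))
        assert exposure_time(33.0, spec) == exposure_time(-33.0, spec)

    def test_out_of_range_angle(self):
        with pytest.raises(ValueError):
            exposure_time(90.0, AcquisitionSpec())


class TestProjection:
    def test_zero_tilt_is_exact_z_sum(self, rng):
        vol = ImageVolume(rng.normal(size=(12, 10, 14)), (1, 1, 1))
        np.testing.assert_allclose(project(vol, 0.0), vol.data.sum(axis=0))

    @pytest.mark.parametrize("theta", [30.0, -45.0])
    @pytest.mark.parametrize("axis_id", [0, 1])
    def test_point_source_lands_at_rotated_position(self, theta, axis_id):
        nz, ny, nx = 32, 24, 28
        data = np.zeros((nz, ny, nx))
        z0, y0, x0 = 20, 8, 10
        data[z0, y0, x0] = 1.0
        p = project(ImageVolume(data, (1, 1, 1)), theta, axis_id=axis_id)
        th = math.radians(theta)
        cz = (nz - 1) / 2
        if axis_id == 0:
            cu = (nx - 1) / 2
            u_pred = (x0 - cu) * math.cos(th) - (z0 - cz) * math.sin(th) + cu
            peak = np.unravel_index(np.argmax(p), p.shape)
            assert peak[0] == y0
            assert abs(peak[1] - u_pred) <= 1.0
        else:
            cu = (ny - 1) / 2
            u_pred = (y0 - cu) * math.cos(th) - (z0 - cz) * math.sin(th) + cu
            peak = np.unravel_index(np.argmax(p), p.shape)
            assert peak[1] == x0
            assert abs(peak[0] - u_pred) <= 1.0

    def test_mass_conserved(self, rng):
        vol = ImageVolume(np.abs(rng.normal(size=(16, 16, 16))), (1, 1, 1))
        assert project(vol, 0.0).sum() == pytest.approx(vol.data.sum(), rel=1e-6)
        # content clear of the field edge stays on the detector at tilt, so
        # mass is conserved within interpolation error
        interior = np.zeros((16, 16, 32))
        interior[4:12, :, 12:20] = np.abs(rng.normal(size=(8, 16, 8)))
        iv = ImageVolume(interior, (1, 1, 1))
        assert project(iv, 30.0).sum() == pytest.approx(interior.sum(), rel=2e-2)

    def test_rotational_consistency(self, rng):
        from scipy import ndimage

        data = np.zeros((33, 9, 33))
        data[12:20, :, 14:22] = 1.0
        data = ndimage.gaussian_filter(data, 1.5)
        vol = ImageVolume(data, (1, 1, 1))
        p_direct = project(vol, 25.0)
        rotated = ndimage.rotate(data, -25.0, axes=(0, 2), reshape=False, order=1)
        p_two_step = project(ImageVolume(rotated, (1, 1, 1)), 0.0)
        err = np.abs(p_direct - p_two_step).max() / p_direct.max()
        assert err < 0.05


class TestTiltSeriesSimulation:
    def test_default_scheme_has_121_projections_per_axis(self):
        spec = AcquisitionSpec()
        assert len(spec.angles) == 121
        vol = ImageVolume(np.ones((4, 8, 8)), (1, 1, 1))
        series = simulate_tilt_series(vol, AcquisitionSpec(increment=10.0), seed=0)
        assert [s.axis_id for s in series] == [0, 1]
        assert len(series[0]) == 13

    def test_noiseless_series_reduces_to_project(self, rng):
        vol = ImageVolume(np.abs(rng.normal(size=(8, 12, 12))), (1, 1, 1))
        spec = AcquisitionSpec(increment=20.0, axes=(0,))
        series, = simulate_tilt_series(vol, spec, seed=0)
        for p, ang in zip(series.projections, series.angles):
            np.testing.assert_allclose(p, project(vol, ang), atol=1e-12)

    def test_shrinkage_reduces_projected_bead_offset(self):
        # two beads separated by the full thickness: the 45-degree projected
        # offset shrinks by the configured total between first and last view
        nz = 40
        vol = np.zeros((nz, 9, 64))
        vol[1, 4, 32] = 1.0
        vol[38, 4, 32] = 1.0
        iv = ImageVolume(vol, (1, 1, 1))
        spec = AcquisitionSpec(tilt_min=-45, tilt_max=45, increment=5.0,
                               axes=(0,), shrinkage_total=0.25)
        series, = simulate_tilt_series(iv, spec, seed=0)

        def offset(p):
            xs = np.nonzero(p[4] > 0.2)[0]
            return xs.max() - xs.min()

        first, last = series.projections[0], series.projections[-1]
        assert offset(last) / offset(first) == pytest.approx(0.75, abs=0.04)


class TestReconstruction:
    def test_point_source_peaks_at_source(self):
        vol = np.zeros((24, 12, 24))
        vol[12, 6, 12] = 1.0
        iv = ImageVolume(vol, (1, 1, 1))
        series, = simulate_tilt_series(iv, AcquisitionSpec(increment=5.0, axes=(0,)),
                                       seed=0)
        rec = wbp_reconstruct(series)
        assert np.unravel_index(np.argmax(rec.data), rec.data.shape) == (12, 6, 12)

    def test_unfiltered_matches_direct_sum_oracle(self, rng):
        nz = ny = nx = 32
        vol = ImageVolume(np.abs(rng.normal(size=(nz, ny, nx))), (1, 1, 1))
        spec = AcquisitionSpec(tilt_min=-60, tilt_max=60, increment=15.0, axes=(0,))
        series, = simulate_tilt_series(vol, spec, seed=0)
        rec = wbp_reconstruct(series, filtered=False)

        # independent oracle: explicit per-voxel bilinear gather of each projection
        oracle = np.zeros((nz, ny, nx))
        cz, cx = (nz - 1) / 2, (nx - 1) / 2
        for p, ang in zip(series.projections, series.angles):
            th = math.radians(ang)
            for z in range(nz):
                for x in range(nx):
                    u = (x - cx) * math.cos(th) - (z - cz) * math.sin(th) + cx
                    i0 = math.floor(u)
                    w = u - i0
                    for i, wt in ((i0, 1 - w), (i0 + 1, w)):
                        if 0 <= i < nx:
                            oracle[z, :, x] += wt * p[:, i]
        np.testing.assert_allclose(rec.data, oracle, rtol=1e-6, atol=1e-9)

    def test_reconstruction_linearity(self, rng):
        vol = ImageVolume(np.abs(rng.normal(size=(16, 8, 16))), (1, 1, 1))
        series, = simulate_tilt_series(vol, AcquisitionSpec(increment=15.0, axes=(0,)),
                                       seed=0)
        rec1 = wbp_reconstruct(series)
        scaled = TiltSeries(series.projections * 3.0, series.angles,
                            axis_id=series.axis_id, pixel_size=series.pixel_size,
                            section_voxels=series.section_voxels)
        rec3 = wbp_reconstruct(scaled)
        np.testing.assert_allclose(rec3.data, 3.0 * rec1.data, rtol=1e-9, atol=1e-12)

    def test_too_few_projections(self):
        with pytest.raises(ValueError):
            wbp_reconstruct(TiltSeries(np.zeros((2, 4, 4)), [-10.0, 10.0],
                                       section_voxels=4))


class TestDualAxis:
    @pytest.fixture(scope="class")
    def two_recs(self):
        rng = np.random.default_rng(0)
        from scipy import ndimage

        truth = ndimage.gaussian_filter(rng.normal(size=(24, 24, 24)), 2.0)
        iv = ImageVolume(truth, (1, 1, 1))
        sA, sB = simulate_tilt_series(iv, AcquisitionSpec(increment=5.0), seed=1)
        return wbp_reconstruct(sA), wbp_reconstruct(sB), truth

    def test_idempotent_on_equal_inputs(self, two_recs):
        rec_a, rec_b, _ = two_recs
        clone = ImageVolume(rec_a.data.copy(), rec_a.voxel_size,
                            meta={"tilt_axis": 1, "tilt_range": (-60.0, 60.0)})
        out = combine_dual_axis(rec_a, clone)
        np.testing.assert_allclose(out.data, rec_a.data, atol=1e-6 * np.abs(rec_a.data).max())

    def test_symmetric_in_arguments(self, two_recs):
        rec_a, rec_b, _ = two_recs
        ab = combine_dual_axis(rec_a, rec_b)
        ba = combine_dual_axis(rec_b, rec_a)
        np.testing.assert_allclose(ab.data, ba.data, atol=1e-9)

    def test_dual_axis_improves_fidelity(self, two_recs):
        rec_a, rec_b, truth = two_recs

        def corr(a, b):
            a = a.ravel() - a.mean()
            b = b.ravel() - b.mean()
            return a @ b / np.sqrt((a @ a) * (b @ b))

        dual = combine_dual_axis(rec_a, rec_b)
        assert corr(dual.data, truth) > max(corr(rec_a.data, truth),
                                            corr(rec_b.data, truth))

    def test_shape_mismatch(self, two_recs):
        rec_a, _, _ = two_recs
        other = ImageVolume(np.zeros((4, 4, 4)), (1, 1, 1))
        with pytest.raises(ValueError):
            combine_dual_axis(rec_a, other)


class TestZResolution:
    def test_printed_arithmetic(self):
        assert corrected_z_resolution(1.8, 2.0, 0.25) == pytest.approx(4.5)

    def test_identity_case(self):
        assert corrected_z_resolution(3.3, 1.0, 0.0) == pytest.approx(3.3)

    def test_closed_form(self):
        assert corrected_z_resolution(2.0, 2.0, 0.10) == pytest.approx(4.4)

    def test_divide_convention(self):
        assert corrected_z_resolution(1.8, 2.0, 0.25, convention="divide") == \
            pytest.approx(4.8)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            corrected_z_resolution(-1.0, 2.0, 0.1)
        with pytest.raises(ValueError):
            corrected_z_resolution(1.8, 2.0, 1.0)


def test_tilt_series_round_trip(tmp_path, rng):
    series = TiltSeries(rng.normal(size=(5, 8, 8)).astype(np.float32),
                        np.arange(-20.0, 21.0, 10.0), axis_id=0, pixel_size=1.5,
                        section_voxels=8)
    path = write_tilt_series(series, tmp_path / "s.mrc")
    assert (tmp_path / "s.tlt").read_text().splitlines()[0] == "-20.00"
    back = read_tilt_series(path, pixel_size=1.5, section_voxels=8)
    np.testing.assert_array_equal(back.projections, series.projections)
    np.testing.assert_allclose(back.angles, series.angles)


def test_angle_monotonicity_enforced():
    with pytest.raises(ValueError):
        TiltSeries(np.zeros((3, 4, 4)), [0.0, -1.0, 1.0])
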