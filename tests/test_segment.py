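"""Stain segmentation, labelling, thickness mapping and SPS morphometry."""

from dataclasses import replace

import numpy as np
import pytest

from gfb3d.io_formats import ImageVolume, LabelVolume
from gfb3d.phantom import (LABEL_LEGEND, GfbPhantomSpec, SpacePhantomSpec,
                           generate_gfb_phantom, generate_space_phantom)
from gfb3d.segment import (invert_backscatter, label_spaces, measure_sps,
                           sps_coverage, threshold_stain, thickness_map)


class TestInvert:
    def test_constant_volume_unchanged(self):
        vol = ImageVolume(np.full((3, 3, 3), 7.0), (1, 1, 1))
        np.testing.assert_array_equal(invert_backscatter(vol).data, vol.data)

    def test_involution(self, rng):
        vol = ImageVolume(rng.normal(size=(4, 5, 6)), (1, 1, 1))
        twice = invert_backscatter(invert_backscatter(vol))
        np.testing.assert_allclose(twice.data, vol.data, atol=1e-12)

    def test_order_reversal(self, rng):
        data = rng.normal(size=(4, 4, 4))
        out = invert_backscatter(data)
        assert np.argmax(data) == np.argmin(out)
        assert np.argmin(data) == np.argmax(out)


class TestThreshold:
    def test_otsu_separates_bimodal_exactly(self, rng):
        data = np.where(rng.random((20, 20, 20)) < 0.3, 200.0, 50.0)
        vol = ImageVolume(data, (1, 1, 1))
        mask, thr = threshold_stain(vol)
        assert 50.0 < thr < 200.0
        np.testing.assert_array_equal(mask, data == 200.0)

    def test_fixed_level_above_max_is_empty(self, rng):
        vol = ImageVolume(rng.normal(size=(4, 4, 4)), (1, 1, 1))
        mask, _ = threshold_stain(vol, method="fixed", level=1e9)
        assert not mask.any()

    def test_constant_volume_otsu_error(self):
        with pytest.raises(ValueError, match="constant"):
            threshold_stain(ImageVolume(np.ones((3, 3, 3)), (1, 1, 1)))

    def test_dice_against_phantom_ground_truth(self, small_gfb_spec):
        # the stain is the brightest of five intensity levels, so the stain
        # mask uses a fixed level between the membrane and stain modes
        noisy_vol, labels, _ = generate_gfb_phantom(small_gfb_spec, seed=4)
        clean_vol, _, _ = generate_gfb_phantom(
            replace(small_gfb_spec, noise_gaussian_sd=0.0), seed=4)
        stain_value = 50.0 + small_gfb_spec.stain_contrast
        truth = clean_vol.data == stain_value
        mask, _ = threshold_stain(noisy_vol, method="fixed", level=165.0)
        dice = 2 * (mask & truth).sum() / (mask.sum() + truth.sum())
        assert dice >= 0.95


class TestLabelSpaces:
    def test_two_disjoint_cubes(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[1:3, 1:3, 1:3] = True
        mask[6:9, 6:9, 6:9] = True
        lv = label_spaces(mask)
        assert lv.labels.max() == 2
        # larger component gets the lower label
        assert (lv.labels == 1).sum() == 27
        assert (lv.labels == 2).sum() == 8

    def test_corner_touching_depends_on_connectivity(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[0:2, 0:2, 0:2] = True
        mask[2:4, 2:4, 2:4] = True
        assert label_spaces(mask, connectivity=26).labels.max() == 1
        assert label_spaces(mask, connectivity=6).labels.max() == 2

    def test_empty_mask(self):
        lv = label_spaces(np.zeros((3, 3, 3), bool))
        assert lv.labels.max() == 0

    def test_partition_stable_under_permutation(self, rng):
        mask = rng.random((12, 12, 12)) < 0.2
        a = label_spaces(mask).labels
        b = label_spaces(mask.copy(order="F")).labels
        np.testing.assert_array_equal(a, b)


class TestThicknessMap:
    def test_uniform_slab(self):
        mask = np.zeros((40, 8, 8), bool)
        mask[10:20] = True  # slab of 10 voxels just above the surface
        thick, gap = thickness_map(mask, surface_z=20, voxel_size=(15.0, 1, 1))
        assert np.all(thick == pytest.approx(150.0))
        assert np.all(gap == pytest.approx(15.0))  # surface voxel itself unstained

    def test_gap_before_stain(self):
        # a 25 nm unstained layer between the membrane and the dense stain
        mask = np.zeros((40, 6, 6), bool)
        mask[10:15] = True
        thick, gap = thickness_map(mask, surface_z=19, voxel_size=(5.0, 1, 1))
        assert np.all(gap == pytest.approx(25.0))
        assert np.all(thick == pytest.approx(25.0))

    def test_no_stain(self):
        mask = np.zeros((10, 4, 4), bool)
        thick, _ = thickness_map(mask, surface_z=5, voxel_size=(2.0, 1, 1))
        assert np.all(thick == 0.0)

    def test_surface_outside_volume(self):
        with pytest.raises(ValueError):
            thickness_map(np.zeros((5, 4, 4), bool), surface_z=7, voxel_size=(1, 1, 1))

    def test_mean_matches_phantom_glycocalyx_thickness(self, small_gfb_spec):
        clean_vol, labels, _ = generate_gfb_phantom(
            replace(small_gfb_spec, noise_gaussian_sd=0.0), seed=4)
        mask = labels.mask("glycocalyx")
        surface = int(small_gfb_spec.membrane_plane / small_gfb_spec.voxel_size[0])
        thick, _ = thickness_map(mask, surface_z=surface,
                                 voxel_size=small_gfb_spec.voxel_size)
        assert thick.mean() == pytest.approx(small_gfb_spec.glycocalyx_thickness,
                                             abs=2 * small_gfb_spec.voxel_size[0])


def _match_records(truth, measured):
    """Pair ground-truth and measured records by nearest (length, depth)."""
    pairs = []
    remaining = list(measured)
    for t in truth:
        best = min(remaining, key=lambda m: abs(m.length_um - t.length_um)
                   + abs(m.depth_nm - t.depth_nm) / 1000.0)
        remaining.remove(best)
        pairs.append((t, best))
    return pairs


class TestMeasureSps:
    def test_recovers_default_phantom_within_one_voxel(self, space_phantom):
        _, labels, truth = space_phantom
        vz, vy, vx = labels.voxel_size
        measured = measure_sps(labels)
        assert len(measured.records) == len(truth.records)
        for t, m in _match_records(truth.records, measured.records):
            assert m.exit_width_nm == pytest.approx(t.exit_width_nm, abs=vz + 1e-9)
            assert m.length_um * 1000 == pytest.approx(t.length_um * 1000, abs=vx + 1e-9)
            assert m.depth_nm == pytest.approx(t.depth_nm, abs=vz + 1e-9)
            assert m.n_exits == t.n_exits

    def test_sealed_space_reports_no_exit(self, space_phantom):
        _, labels, truth = space_phantom
        measured = measure_sps(labels)
        sealed_truth = sum(1 for r in truth.records if r.n_exits == 0)
        sealed_meas = sum(1 for r in measured.records if r.n_exits == 0)
        assert sealed_meas == sealed_truth
        for r in measured.records:
            assert (r.exit_width_nm == 0) == (r.n_exits == 0)

    def test_two_disjoint_spaces_two_records(self):
        labels = np.full((20, 20, 40), 5, dtype=np.int16)  # podocyte body
        labels[5:10, 5:15, 5:15] = 6
        labels[5:10, 5:15, 25:35] = 6
        lv = LabelVolume(labels, dict(LABEL_LEGEND), (10.0, 10.0, 10.0))
        table = measure_sps(lv)
        assert len(table.records) == 2
        assert table.records[0].sps_id != table.records[1].sps_id

    def test_no_sps_label_empty_table(self):
        lv = LabelVolume(np.zeros((4, 4, 4), np.int16), {0: "resin"}, (1, 1, 1))
        assert measure_sps(lv).records == []


class TestCoverage:
    def _labels(self, frac_sps):
        nz, ny, nx = 20, 10, 40
        labels = np.full((nz, ny, nx), 5, dtype=np.int16)
        labels[-2:] = 4  # GBM at the bottom; surface on top of it
        n_sps = int(round(frac_sps * nx))
        labels[10:16, :, :n_sps] = 6  # SPS above part of the surface
        labels[10:16, :, n_sps:] = 8  # PUS above the rest
        return LabelVolume(labels, dict(LABEL_LEGEND), (1, 1, 1))

    def test_full_coverage(self):
        assert sps_coverage(self._labels(1.0), surface_z=17) == pytest.approx(1.0)

    def test_half_coverage(self):
        assert sps_coverage(self._labels(0.5), surface_z=17) == pytest.approx(0.5, abs=0.02)

    def test_no_sps(self):
        lv = self._labels(0.0)
        assert sps_coverage(lv, surface_z=17) == pytest.approx(0.0)


def test_morphometry_recovery_over_random_phantoms():
    """Exit width, length and depth recovered within one voxel for exits >= 3 voxels."""
    rng = np.random.default_rng(42)
    checked = 0
    for trial in range(10):
        geoms = []
        for _ in range(2):
            w = float(rng.choice([0.0, float(rng.uniform(100, 1500))]))
            depth = float(rng.uniform(max(w, 100.0) + 50.0, 1800.0))
            geoms.append((w, float(rng.uniform(2.0, 8.0)), depth))
        spec = SpacePhantomSpec(sps_geometries=geoms)
        _, labels, truth = generate_space_phantom(spec, seed=trial)
        measured = measure_sps(labels)
        vz, vy, vx = spec.voxel_size
        for t, m in _match_records(truth.records, measured.records):
            assert m.exit_width_nm == pytest.approx(t.exit_width_nm, abs=vz + 1e-9)
            assert m.length_um * 1000 == pytest.approx(t.length_um * 1000, abs=vx + 1e-9)
            assert m.depth_nm == pytest.approx(t.depth_nm, abs=vz + 1e-9)
            checked += 1
    assert checked == 20
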