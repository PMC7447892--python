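"""Mask stacking, 3D labeling, exclusion filters, isotropic resampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flocfrac.reconstruction import (BinaryVolume, LabeledVolume,
                                     apply_filters, extract_particles,
                                     label_components, remove_border_touching,
                                     remove_pillars, remove_small,
                                     resample_isotropic, stack_masks)
from flocfrac.stack_io import VoxelGeometry

from .oracles import flood_fill_components, same_partition


def volume_of(mask3d, geometry=None):
    return BinaryVolume(np.asarray(mask3d, dtype=bool),
                        geometry or VoxelGeometry(1, 1, 1))


def labeled_from_mask(mask3d, connectivity=26):
    return label_components(volume_of(mask3d), connectivity)


class TestStackMasks:
    def test_disk_masks_stack_to_cylinder(self, iso_geometry):
        yy, xx = np.mgrid[:16, :16]
        disk = (yy - 8) ** 2 + (xx - 8) ** 2 <= 25
        vol = stack_masks([disk] * 3, iso_geometry)
        assert vol.shape == (3, 16, 16)
        assert vol.count() == 3 * disk.sum()

    def test_dimension_mismatch_names_slice(self, iso_geometry):
        with pytest.raises(ValueError, match="mask 1"):
            stack_masks([np.zeros((4, 4), bool), np.zeros((5, 4), bool)],
                        iso_geometry)

    def test_empty_list_rejected(self, iso_geometry):
        with pytest.raises(ValueError):
            stack_masks([], iso_geometry)


class TestLabelComponents:
    def test_corner_touching_cubes_depend_on_connectivity(self):
        vol = np.zeros((8, 8, 8), dtype=bool)
        vol[0:3, 0:3, 0:3] = True
        vol[3:6, 3:6, 3:6] = True  # shares only the corner voxel diagonal
        assert labeled_from_mask(vol, connectivity=26).n_labels == 1
        assert labeled_from_mask(vol, connectivity=6).n_labels == 2

    def test_empty_volume_has_no_components(self):
        assert labeled_from_mask(np.zeros((4, 4, 4), bool)).n_labels == 0

    def test_filled_cube_is_one_component(self):
        lab = labeled_from_mask(np.ones((64, 64, 64), bool))
        assert lab.n_labels == 1
        assert lab.sizes()[0] == 64 ** 3

    def test_invalid_connectivity(self):
        with pytest.raises(ValueError):
            labeled_from_mask(np.ones((2, 2, 2), bool), connectivity=8)

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_agrees_with_flood_fill_oracle(self, connectivity, rng):
        for _ in range(10):
            vol = rng.random((10, 10, 10)) < 0.25
            ours = labeled_from_mask(vol, connectivity).labels
            oracle = flood_fill_components(vol, connectivity)
            assert same_partition(ours, oracle)


class TestRemoveSmall:
    def test_five_thousand_voxel_cut(self):
        # components of 10, 5000 and 12000 voxels as flat slabs
        vol = np.zeros((5, 200, 200), dtype=bool)
        vol[0, :1, :10] = True
        vol[2, :25, :200] = True
        vol[4, :60, :200] = True
        lab = labeled_from_mask(vol, connectivity=6)
        assert sorted(lab.sizes()) == [10, 5000, 12000]
        kept = remove_small(lab, 5000)
        assert kept.n_labels == 2

    def test_min_zero_is_identity(self):
        lab = labeled_from_mask(np.ones((3, 3, 3), bool))
        out = remove_small(lab, 0)
        assert np.array_equal(out.labels, lab.labels)

    def test_threshold_above_everything_empties(self):
        lab = labeled_from_mask(np.ones((3, 3, 3), bool))
        assert remove_small(lab, 1000).n_labels == 0


class TestRemoveBorderTouching:
    def test_interior_cube_survives(self):
        vol = np.zeros((20, 20, 20), dtype=bool)
        vol[8:13, 8:13, 8:13] = True
        assert remove_border_touching(labeled_from_mask(vol)).n_labels == 1

    def test_z_face_contact_removes(self):
        vol = np.zeros((20, 20, 20), dtype=bool)
        vol[0:5, 8:13, 8:13] = True  # touches first z slice
        assert remove_border_touching(labeled_from_mask(vol)).n_labels == 0

    def test_full_foreground_removed(self):
        assert remove_border_touching(
            labeled_from_mask(np.ones((5, 5, 5), bool))).n_labels == 0


class TestRemovePillars:
    def test_constant_footprint_column_removed(self):
        vol = np.zeros((30, 40, 40), dtype=bool)
        vol[:, 10:15, 10:15] = True  # identical 5x5 footprint in every slice
        assert remove_pillars(labeled_from_mask(vol)).n_labels == 0

    def test_partial_z_span_kept(self):
        vol = np.zeros((30, 40, 40), dtype=bool)
        vol[5:17, 10:15, 10:15] = True  # 40% of slices
        assert remove_pillars(labeled_from_mask(vol)).n_labels == 1

    def test_drifting_rod_kept(self):
        # spans all slices but footprint drifts: low per-slice Jaccard
        vol = np.zeros((30, 40, 60), dtype=bool)
        for k in range(30):
            vol[k, 10:15, k:k + 5] = True
        lab = labeled_from_mask(vol)
        assert remove_pillars(lab).n_labels == 1

    def test_threshold_validation(self):
        lab = labeled_from_mask(np.ones((2, 2, 2), bool))
        with pytest.raises(ValueError):
            remove_pillars(lab, min_z_span_fraction=1.5)


class TestExtractParticles:
    def test_sorted_and_conserving(self, rng):
        vol = rng.random((15, 15, 15)) < 0.2
        lab = labeled_from_mask(vol)
        particles = extract_particles(lab, condition="demo")
        counts = [p.voxel_count for p in particles]
        assert counts == sorted(counts, reverse=True)
        assert sum(counts) == int((lab.labels > 0).sum())
        assert all(p.condition == "demo" for p in particles)

    def test_empty_labeling_yields_empty_list(self):
        assert extract_particles(labeled_from_mask(np.zeros((3, 3, 3), bool))) == []


class TestResampleIsotropic:
    def test_acquisition_anisotropy_doubles_slices(self, paper_geometry):
        vol = BinaryVolume(np.ones((10, 4, 4), bool), paper_geometry)
        iso = resample_isotropic(vol)  # dz/dx = 2.152 -> factor 2
        assert iso.shape == (20, 4, 4)
        assert iso.count() == 2 * vol.count()
        assert iso.geometry.dz == pytest.approx(paper_geometry.dz / 2)

    def test_isotropic_volume_passes_through(self, iso_geometry):
        vol = BinaryVolume(np.ones((4, 4, 4), bool), iso_geometry)
        assert resample_isotropic(vol) is vol

    def test_cylinder_keeps_footprint(self, paper_geometry):
        yy, xx = np.mgrid[:12, :12]
        disk = (yy - 6) ** 2 + (xx - 6) ** 2 <= 16
        vol = BinaryVolume(np.stack([disk] * 5), paper_geometry)
        iso = resample_isotropic(vol)
        assert iso.shape[0] == 10
        assert np.array_equal(iso.voxels.any(axis=0), disk)

    def test_downsampling_is_warned_noop(self, caplog):
        vol = BinaryVolume(np.ones((4, 4, 4), bool), VoxelGeometry(1, 1, 0.25))
        with caplog.at_level("WARNING"):
            out = resample_isotropic(vol)
        assert out is vol
        assert "skipped" in caplog.text


class TestFilterInvariants:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_filters_never_add_voxels_and_stay_compact(self, seed):
        r = np.random.default_rng(seed)
        vol = r.random((12, 12, 12)) < 0.2
        lab = labeled_from_mask(vol)
        before = int((lab.labels > 0).sum())
        out = apply_filters(lab, min_voxels=3)
        assert int((out.labels > 0).sum()) <= before
        present = np.unique(out.labels)
        present = present[present > 0]
        assert list(present) == list(range(1, out.n_labels + 1))
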