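import numpy as np
import pytest

from ctpos.imaging_io import VoxelImage
from ctpos.segmentation import label_objects, nucleus_object, threshold_channel
from ctpos.synthetic_data import NucleusSpec, _ellipsoid_mask


def _img(arr, voxel=(0.3, 0.2, 0.2)):
    return VoxelImage(np.asarray(arr, dtype=np.uint8), voxel, "test")


def test_otsu_separates_a_two_level_image():
    data = np.zeros((4, 6, 6), dtype=np.uint8)
    data[1:3, 2:5, 2:5] = 200
    mask = threshold_channel(_img(data))
    np.testing.assert_array_equal(mask, data == 200)


def test_fixed_threshold_is_inclusive():
    data = np.zeros((2, 2, 2), dtype=np.uint8)
    data[0, 0, 0] = 99
    data[0, 0, 1] = 100
    mask = threshold_channel(_img(data), method=100)
    assert not mask[0, 0, 0]
    assert mask[0, 0, 1]


def test_otsu_on_constant_image_advises_fixed_threshold():
    with pytest.raises(ValueError, match="fixed"):
        threshold_channel(_img(np.full((3, 3, 3), 7)))


def _two_cubes(gap=2):
    mask = np.zeros((6, 6, 14), dtype=bool)
    mask[1:5, 1:5, 1:5] = True  # 64 voxels
    mask[1:5, 1:5, 5 + gap : 9 + gap] = True  # 64 voxels
    return mask


@pytest.mark.parametrize("min_voxels,expected", [(50, 2), (65, 0)])
def test_min_voxel_filter(min_voxels, expected):
    objects = label_objects(_two_cubes(), min_voxels=min_voxels)
    assert len(objects) == expected


def test_objects_ordered_by_size_then_position():
    mask = np.zeros((4, 4, 20), dtype=bool)
    mask[0:2, 0:2, 0:2] = True  # 8 voxels at x=0
    mask[0:2, 0:2, 10:13] = True  # 12 voxels at x=10
    mask[0:2, 0:2, 16:18] = True  # 8 voxels at x=16
    objects = label_objects(mask, min_voxels=1)
    sizes = [o.n_voxels for o in objects]
    assert sizes == [12, 8, 8]
    # the two 8-voxel ties break on the smaller minimum index
    assert objects[1].voxel_indices.min(axis=0)[2] == 0
    assert objects[2].voxel_indices.min(axis=0)[2] == 16


def test_sum_of_object_volumes_matches_mask_at_min_voxels_one():
    rng = np.random.default_rng(5)
    vox = (0.3, 0.2, 0.2)
    voxvol = float(np.prod(vox))
    for _ in range(5):
        mask = rng.random((8, 10, 10)) < 0.25
        objects = label_objects(mask, min_voxels=1, voxel_size=vox)
        total = sum(o.volume_um3 for o in objects)
        assert total == pytest.approx(mask.sum() * voxvol)
        filtered = label_objects(mask, min_voxels=4, voxel_size=vox)
        assert sum(o.volume_um3 for o in filtered) <= total + 1e-9


def test_centroid_equals_center_of_mass_on_uniform_objects():
    mask = np.zeros((5, 7, 7), dtype=bool)
    mask[1:4, 2:6, 2:5] = True
    intensities = np.where(mask, 180, 0).astype(np.uint8)
    (obj,) = label_objects(mask, min_voxels=1, voxel_size=(0.3, 0.1, 0.1),
                           intensities=intensities)
    assert obj.centroid_um == pytest.approx(obj.center_of_mass_um)


def test_nucleus_picks_largest_component_over_debris():
    mask = np.zeros((10, 20, 20), dtype=bool)
    mask[2:8, 2:12, 2:12] = True
    mask[1:3, 15:18, 15:18] = True  # debris
    obj = nucleus_object(mask, voxel_size=(0.3, 0.2, 0.2))
    assert obj.n_voxels == 6 * 10 * 10


def test_nucleus_holes_filled_to_analytic_ellipsoid_volume():
    vox = (0.25, 0.15, 0.15)
    nucleus = NucleusSpec((3.0, 3.0, 3.0), (2.4, 2.4, 2.4))
    mask = _ellipsoid_mask((25, 41, 41), vox, nucleus.center_um,
                           nucleus.semi_axes_um, nucleus.rotation())
    holey = mask.copy()
    holey[10:14, 16:24, 16:24] = False  # interior cavity
    obj = nucleus_object(holey, voxel_size=vox)
    assert obj.volume_um3 == pytest.approx(nucleus.volume_um3, rel=0.05)
    assert obj.n_voxels == mask.sum()


def test_planted_sphere_volume_within_five_percent():
    """Volume of a rasterized sphere of radius >= 10x the largest voxel
    dimension matches (4/3)πr³ within 5 %."""
    vox = (0.2, 0.1, 0.1)
    r = 2.0  # = 10 x max voxel dim
    nucleus = NucleusSpec((2.6, 2.6, 2.6), (r, r, r))
    mask = _ellipsoid_mask((27, 53, 53), vox, nucleus.center_um,
                           nucleus.semi_axes_um, nucleus.rotation())
    obj = nucleus_object(mask, voxel_size=vox)
    assert obj.volume_um3 == pytest.approx(4 / 3 * np.pi * r**3, rel=0.05)


def test_empty_mask_is_an_error():
    with pytest.raises(ValueError, match="empty"):
        nucleus_object(np.zeros((4, 4, 4), dtype=bool))
    assert label_objects(np.zeros((4, 4, 4), dtype=bool)) == []
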