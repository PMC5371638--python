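import math

import numpy as np
import pytest

from ctpos.geometry import (
    ShellIndex,
    anchor_surface_voxels,
    lamina_distance,
    radial_distance,
    shell_of,
    volumes_by_shell,
)
VOX = (0.34, 0.105, 0.105)  # default confocal calibration
ISO = (0.25, 0.25, 0.25)


def sphere_mask(radius_um, voxel_size):
    """Boolean raster of a centered sphere plus its center point (μm)."""
    vox = np.asarray(voxel_size)
    margin = 3 * vox
    center = radius_um + margin
    shape = tuple(
        int(np.ceil(2 * (radius_um + margin[i]) / vox[i])) + 1 for i in range(3)
    )
    zz, yy, xx = np.meshgrid(
        *(np.arange(shape[i]) * vox[i] for i in range(3)), indexing="ij"
    )
    d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    return d2 <= radius_um**2, tuple(center)


@pytest.fixture(scope="module")
def sphere10():
    """Radius-10 μm sphere at the default anisotropic calibration."""
    return sphere_mask(10.0, VOX)


def test_degenerate_b_equals_a_gives_zero(sphere10):
    mask, center = sphere10
    rm = radial_distance(mask, center, center, VOX)
    assert rm.rd_percent == 0.0
    assert rm.degenerate
    assert rm.C_um is None


def test_sphere_half_radius_measures_fifty_percent(sphere10):
    mask, center = sphere10
    b = (center[0], center[1], center[2] + 5.0)
    rm = radial_distance(mask, center, b, VOX)
    assert rm.rd_percent == pytest.approx(50.0, abs=2.0)
    assert rm.X_um == pytest.approx(5.0)
    assert rm.Y_um == pytest.approx(10.0, abs=0.2)


def test_boundary_territory_measures_hundred_percent(sphere10):
    mask, center = sphere10
    b = (center[0], center[1] + 10.0, center[2])
    rm = radial_distance(mask, center, b, VOX)
    assert rm.rd_percent == pytest.approx(100.0, abs=2.0)


def test_rd_strictly_increases_along_a_fixed_ray(sphere10):
    mask, center = sphere10
    u = np.array([0.2, 0.5, 0.8])
    u /= np.linalg.norm(u)
    values = []
    for dist in (1.0, 3.0, 5.0, 7.0, 9.0):
        b = np.asarray(center) + dist * u
        values.append(radial_distance(mask, center, tuple(b), VOX).rd_percent)
    assert all(0 <= v <= 100 for v in values)
    assert all(a < b for a, b in zip(values, values[1:]))


def test_center_outside_mask_is_an_error(sphere10):
    mask, center = sphere10
    outside = (0.1, 0.1, 0.1)
    with pytest.raises(ValueError, match="outside"):
        radial_distance(mask, outside, center, VOX)


def test_mask_touching_border_is_an_error():
    mask = np.ones((8, 8, 8), dtype=bool)
    center = (0.875, 0.875, 0.875)
    with pytest.raises(ValueError, match="border"):
        radial_distance(mask, center, (0.875, 0.875, 1.3), ISO)


def test_rotation_invariance_of_rd():
    """Rotating mask and points together changes %RD by < 1 point."""
    mask, center = sphere_mask(4.0, ISO)
    u = np.array([0.0, 0.6, 0.8])
    b = np.asarray(center) + 2.5 * u
    rd0 = radial_distance(mask, center, tuple(b), ISO).rd_percent
    # 90-degree rotation about z: (z, y, x) -> (z, x, -y) on this cubic grid
    mask_rot = np.rot90(mask, k=1, axes=(1, 2))
    b_rot = np.asarray(center) + 2.5 * np.array([0.0, 0.8, -0.6])
    rd1 = radial_distance(mask_rot, center, tuple(b_rot), ISO).rd_percent
    assert abs(rd0 - rd1) < 1.0


@pytest.mark.parametrize(
    "rd,expected",
    [
        (0.0, ShellIndex.I),
        (10.0, ShellIndex.I),
        (20.0, ShellIndex.I),
        (20.0001, ShellIndex.II),
        (40.0, ShellIndex.II),
        (60.0, ShellIndex.III),
        (80.0, ShellIndex.IV),
        (99.0, ShellIndex.V),
        (100.0, ShellIndex.V),
    ],
)
def test_shell_convention_upper_inclusive(rd, expected):
    assert shell_of(rd) == expected


@pytest.mark.parametrize("bad", [-0.1, 100.1])
def test_shell_rejects_out_of_range(bad):
    with pytest.raises(ValueError):
        shell_of(bad)


def _exhaustive_surface_distance(cm, mask, voxel_size):
    """Independent oracle: python-loop min over all surface voxel centers."""
    surface = anchor_surface_voxels(mask)
    best = math.inf
    vox = np.asarray(voxel_size)
    cm = np.asarray(cm, dtype=float)
    for idx in surface:
        d = np.sqrt(((idx * vox - cm) ** 2).sum())
        best = min(best, d)
    return best


def test_lamina_distance_zero_on_surface_voxel_center():
    mask = np.zeros((6, 6, 6), dtype=bool)
    mask[2:4, 2:4, 2:4] = True
    cm = (2 * 0.3, 2 * 0.2, 2 * 0.2)  # a corner voxel of the cube = surface
    lm = lamina_distance(cm, mask, (0.3, 0.2, 0.2))
    assert lm.distance_um == 0.0


def test_lamina_distance_matches_exhaustive_oracle_exactly():
    rng = np.random.default_rng(42)
    vox = (0.3, 0.2, 0.2)
    for _ in range(8):
        mask = np.zeros((7, 8, 8), dtype=bool)
        blob = rng.random((5, 6, 6)) < 0.4
        mask[1:6, 1:7, 1:7] = blob
        if not mask.any():
            continue
        cm = tuple(rng.uniform(0.2, 1.4, size=3))
        lm = lamina_distance(cm, mask, vox)
        assert lm.distance_um == _exhaustive_surface_distance(cm, mask, vox)


def test_spherical_rim_distance_matches_analytic():
    """CM at the center of a lamina-like spherical rim of inner radius
    10 μm measures 10 μm to the rim surface, within half a voxel diagonal."""
    vox = np.array((0.34, 0.21, 0.21))  # coarser xy to keep the test light
    center = 10.6 + 3 * vox
    shape = tuple(int(np.ceil(2 * center[i] / vox[i])) + 1 for i in range(3))
    zz, yy, xx = np.meshgrid(
        *(np.arange(shape[i]) * vox[i] for i in range(3)), indexing="ij"
    )
    d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    rim = (d2 <= 10.6**2) & (d2 > 10.0**2)  # anchor outside the r=10 boundary
    center = tuple(center)
    lm = lamina_distance(center, rim, vox)
    half_diag = 0.5 * float(np.linalg.norm(vox))
    assert lm.distance_um == pytest.approx(10.0, abs=half_diag)
    assert lm.distance_um >= 10.0  # rim voxels all lie beyond the boundary


def test_empty_anchor_is_an_error():
    with pytest.raises(ValueError, match="empty"):
        lamina_distance((1, 1, 1), np.zeros((4, 4, 4), dtype=bool), ISO)


def test_volumes_by_shell_grouping(sphere10):
    mask, center = sphere10
    rms = [
        radial_distance(mask, center, (center[0], center[1], center[2] + 5.0), VOX)
        for _ in range(3)
    ]
    groups = volumes_by_shell([(rm, 2.5) for rm in rms])
    assert set(groups) == {ShellIndex.III}
    assert groups[ShellIndex.III] == [2.5, 2.5, 2.5]
    assert volumes_by_shell([]) == {}
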