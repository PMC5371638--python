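import numpy as np
import pytest

from ctpos.expression import filter_deregulated, gene_ids, overlap
from ctpos.geometry import radial_distance
from ctpos.segmentation import label_objects, nucleus_object, threshold_channel
from ctpos.synthetic_data import (
    AcquisitionSpec,
    ChromosomeSimSpec,
    ExpressionSimSpec,
    NucleusSpec,
    TerritorySpec,
    centered_nucleus,
    simulate_cell,
    simulate_expression_table,
    simulate_knockdown_pair,
    surface_distance_along,
)


def _flood_fill_count(mask):
    """Brute-force 26-connected component count (independent oracle)."""
    mask = mask.copy()
    shape = mask.shape
    count = 0
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    seeds = np.argwhere(mask)
    visited = np.zeros(shape, dtype=bool)
    for seed in seeds:
        seed = tuple(seed)
        if visited[seed] or not mask[seed]:
            continue
        count += 1
        stack = [seed]
        visited[seed] = True
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in offsets:
                n = (z + dz, y + dy, x + dx)
                if (
                    0 <= n[0] < shape[0]
                    and 0 <= n[1] < shape[1]
                    and 0 <= n[2] < shape[2]
                    and mask[n]
                    and not visited[n]
                ):
                    visited[n] = True
                    stack.append(n)
    return count


def test_zero_fractional_rd_places_centroid_at_nucleus_center(noiseless_acq):
    nucleus, shape = centered_nucleus((3.0, 3.0, 3.0), noiseless_acq)
    stack, truth = simulate_cell(
        nucleus, [TerritorySpec("CT", 0.0, (0, 0, 1))], noiseless_acq, shape=shape
    )
    np.testing.assert_allclose(
        truth.territories[0]["centroid_um"], nucleus.center_um, atol=1e-12
    )


def test_half_radius_placement_on_a_sphere():
    # sphere of radius 10 μm: fractional_rd 0.5 along +x sits 5 μm out
    nucleus = NucleusSpec((12, 12, 12), (10, 10, 10))
    assert surface_distance_along(nucleus, (0, 0, 1.0)) == pytest.approx(10.0)
    acq = AcquisitionSpec(voxel_size_um=(0.5, 0.5, 0.5), shot_noise=False,
                          read_noise_sd=0, psf_sigma_um=(0, 0, 0), seed=0)
    stack, truth = simulate_cell(
        nucleus, [TerritorySpec("CT", 0.5, (0, 0, 1.0))], acq
    )
    centroid = np.asarray(truth.territories[0]["centroid_um"])
    assert np.linalg.norm(centroid - np.asarray(nucleus.center_um)) == pytest.approx(5.0)


def test_two_planted_copies_yield_two_components_noiseless(noiseless_acq):
    nucleus, shape = centered_nucleus((3.0, 3.6, 3.4), noiseless_acq)
    territories = [
        TerritorySpec("CT19", 0.5, (0, 0, 1.0), copy_index=1),
        TerritorySpec("CT19", 0.6, (0, -1.0, 0), copy_index=2),
    ]
    stack, truth = simulate_cell(nucleus, territories, noiseless_acq, shape=shape)
    mask = stack["CT19"].intensities > 0
    assert _flood_fill_count(mask) == 2
    assert truth.copy_number["CT19"] == 2


def test_rendered_volume_hits_target_within_five_percent(coarse_acq):
    nucleus, shape = centered_nucleus((3.0, 3.6, 3.4), coarse_acq)
    for target in (1.5, 3.0, 6.0):
        _, truth = simulate_cell(
            nucleus,
            [TerritorySpec("CT", 0.4, (0, 1.0, 0), target_volume_um3=target)],
            coarse_acq,
            shape=shape,
        )
        rendered = truth.territories[0]["rendered_volume_um3"]
        assert abs(rendered - target) / target < 0.05


def test_identical_seeds_give_bit_identical_stacks(coarse_acq, small_cell):
    stack_a, truth_a, nucleus = small_cell
    territories = [
        TerritorySpec("CT19", 0.5, (0.0, 0.0, 1.0), copy_index=1),
        TerritorySpec("CT19", 0.6, (0.0, -1.0, 0.0), copy_index=2),
    ]
    stack_b, truth_b = simulate_cell(
        nucleus, territories, coarse_acq, lamina_thickness_um=0.5,
        shape=stack_a.shape,
    )
    for name in stack_a.names:
        np.testing.assert_array_equal(
            stack_a[name].intensities, stack_b[name].intensities
        )
    assert truth_a.to_dict() == truth_b.to_dict()


def test_noiseless_roundtrip_recovers_planted_centroids_subvoxel(noiseless_acq):
    """With PSF off and noise off, segmentation + centroid lands within
    half a voxel diagonal of every planted territory centroid."""
    nucleus, shape = centered_nucleus((3.0, 3.6, 3.4), noiseless_acq)
    territories = [
        TerritorySpec("CT", 0.3, (0, 0, 1.0), copy_index=1),
        TerritorySpec("CT", 0.7, (0, -1.0, 0), copy_index=2),
    ]
    stack, truth = simulate_cell(nucleus, territories, noiseless_acq, shape=shape)
    vox = np.asarray(noiseless_acq.voxel_size_um)
    half_diag = 0.5 * float(np.linalg.norm(vox))
    objects = label_objects(
        stack["CT"].intensities > 0, 20, vox, stack["CT"].intensities
    )
    assert len(objects) == 2
    planted = [np.asarray(t["centroid_um"]) for t in truth.territories]
    for obj in objects:
        d = min(np.linalg.norm(np.asarray(obj.centroid_um) - p) for p in planted)
        assert d <= half_diag


def test_measured_rd_increases_with_planted_fraction(noiseless_acq):
    """Monotonicity: along a fixed ray in a fixed nucleus, a larger planted
    fractional radial position always measures as a larger %RD."""
    nucleus, shape = centered_nucleus((3.0, 3.6, 3.4), noiseless_acq)
    measured = []
    for frac in (0.1, 0.3, 0.5, 0.7, 0.9):
        stack, _ = simulate_cell(
            nucleus,
            [TerritorySpec("CT", frac, (0, 0.6, 0.8), target_volume_um3=1.0)],
            noiseless_acq,
            shape=shape,
        )
        vox = stack.voxel_size
        nuc = nucleus_object(stack["dapi"].intensities > 0, vox)
        filled = np.zeros(stack.shape, bool)
        filled[tuple(nuc.voxel_indices.T)] = True
        objs = label_objects(stack["CT"].intensities > 0, 20, vox)
        assert len(objs) == 1
        rm = radial_distance(filled, nuc.centroid_um, objs[0].centroid_um, vox)
        measured.append(rm.rd_percent)
    assert all(a < b for a, b in zip(measured, measured[1:]))


def test_lamina_rim_sits_at_nucleus_boundary(small_cell):
    stack, truth, nucleus = small_cell
    rim = stack["lamina"].intensities > 100
    body = stack["dapi"].intensities > 100
    assert rim.any()
    assert (rim & body).sum() / rim.sum() > 0.9  # rim is part of the body


def test_out_of_range_specs_rejected(coarse_acq):
    with pytest.raises(ValueError, match="outside"):
        TerritorySpec("CT", 1.2, (0, 0, 1))
    with pytest.raises(ValueError):
        TerritorySpec("CT", -0.1, (0, 0, 1))
    with pytest.raises(ValueError):
        NucleusSpec((5, 5, 5), (3, 0, 3))
    nucleus = NucleusSpec((1.0, 1.0, 1.0), (3.0, 3.0, 3.0))
    with pytest.raises(ValueError, match="margin"):
        simulate_cell(nucleus, [], coarse_acq, shape=(20, 40, 40))


# ---- expression tables ----


def _chrom(label="1", n=1000, frac=1.0):
    return ChromosomeSimSpec(label, n, 100.0, frac)


def test_zero_planted_fraction_gives_empty_deregulated_set():
    records, truth = simulate_expression_table(
        ExpressionSimSpec([_chrom(frac=0.0)], seed=1)
    )
    up, down = filter_deregulated(records)
    assert up == [] and down == []
    assert truth["dereg_ids"] == set()


def test_exact_planted_count_passes_filter():
    """1000 coding genes at planted 1.0 % -> exactly 10 rows pass the
    |FC|>=2, p<0.05 filter (checked by brute force on the emitted table)."""
    records, truth = simulate_expression_table(
        ExpressionSimSpec([_chrom(frac=1.0)], seed=2)
    )
    assert len(records) == 1000
    brute = {
        g.gene_id for g in records if abs(g.fold_change) >= 2.0 and g.p_value < 0.05
    }
    assert len(brute) == 10
    assert brute == truth["dereg_ids"]


def test_planted_common_set_recovered_by_overlap():
    chroms = [_chrom(str(i), 2000, 0.0) for i in range(1, 5)]
    a, b, truth = simulate_knockdown_pair(chroms, 10, 15, 12, 10, n_common=7, seed=3)
    ids_a = gene_ids(sum(filter_deregulated(a), []))
    ids_b = gene_ids(sum(filter_deregulated(b), []))
    assert overlap(ids_a, ids_b) == (18, 15, 7)
    assert ids_a & ids_b == truth["common_ids"]


def test_planted_fraction_above_100_rejected():
    with pytest.raises(ValueError, match="100"):
        ChromosomeSimSpec("1", 100, 10.0, 101.0)


def test_expression_tables_reproducible():
    spec = ExpressionSimSpec([_chrom(frac=0.5)], seed=9)
    a, _ = simulate_expression_table(spec)
    b, _ = simulate_expression_table(spec)
    assert a == b
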