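"""Planted-truth recovery experiments and null calibrations.

Each function simulates a study-scale synthetic experiment, runs the full
measurement chain (render -> segment -> measure -> test) and reports how
well the planted ground truth is recovered.  They are the package's own
validation battery: the same routines back the test suite and the
results-reproduction script.
"""

from __future__ import annotations

import numpy as np

from .geometry import radial_distance
from .population_stats import ShellDistribution, compare_shell_distributions, ks_two_sample
from .segmentation import label_objects, nucleus_object, threshold_channel
from .synthetic_data import (
    AcquisitionSpec,
    TerritorySpec,
    centered_nucleus,
    simulate_cell,
    simulate_locus_distances,
    well_separated_directions,
)

__all__ = [
    "rd_recovery_experiment",
    "ploidy_recovery_experiment",
    "shell_null_calibration",
    "ks_power_experiment",
]

_SEMI_AXES_UM = (3.2, 5.5, 5.0)  # flattened epithelial-like nucleus


def _simulate_one_cell(rng, territories_fn, acq_kwargs=None):
    axes = tuple(a * (1.0 + rng.uniform(-0.08, 0.08)) for a in _SEMI_AXES_UM)
    orientation = tuple(rng.uniform(0, 2 * np.pi, size=3))
    acq = AcquisitionSpec(seed=int(rng.integers(2**31)), **(acq_kwargs or {}))
    nucleus, shape = centered_nucleus(axes, acq, orientation_rad=orientation)
    territories = territories_fn(rng, nucleus)
    return simulate_cell(nucleus, territories, acq, shape=shape)


def _measure_territories(stack, channel: str, min_voxels: int = 50):
    vox = stack.voxel_size
    nuc_img = stack["dapi"]
    nucleus = nucleus_object(threshold_channel(nuc_img), vox, nuc_img.intensities)
    filled = np.zeros(stack.shape, dtype=bool)
    filled[tuple(nucleus.voxel_indices.T)] = True
    img = stack[channel]
    objects = label_objects(threshold_channel(img), min_voxels, vox, img.intensities, channel)
    measurements = [
        radial_distance(filled, nucleus.centroid_um, obj.centroid_um, vox)
        for obj in objects
    ]
    return nucleus, objects, measurements


def rd_recovery_experiment(
    n_cells: int = 100,
    rd_range: tuple[float, float] = (0.05, 0.95),
    seed: int = 0,
) -> dict:
    """Plant one territory per cell at a uniform fractional radial position
    and recover its %RD through the full imaging + measurement chain.

    Returns the mean and max absolute error between measured %RD and the
    planted 100*fractional_rd, over ``n_cells`` cells at the default
    confocal calibration.
    """
    rng = np.random.default_rng(seed)
    errors = []
    for _ in range(n_cells):
        frac = float(rng.uniform(*rd_range))
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)

        def territories(_rng, _nucleus, frac=frac, direction=direction):
            return [TerritorySpec("CT", frac, tuple(direction))]

        stack, truth = _simulate_one_cell(rng, territories)
        _, objects, measurements = _measure_territories(stack, "CT")
        if len(measurements) != 1:
            raise RuntimeError(
                f"expected one recovered territory, found {len(measurements)}"
            )
        planted = truth.territories[0]["planted_rd_percent"]
        errors.append(abs(measurements[0].rd_percent - planted))
    errors = np.asarray(errors)
    return {
        "n_cells": n_cells,
        "mean_abs_error_pp": float(errors.mean()),
        "max_abs_error_pp": float(errors.max()),
    }


def ploidy_recovery_experiment(
    n_cells: int = 100,
    gain_fraction: float = 0.30,
    seed: int = 0,
) -> dict:
    """Plant an exact fraction of 3-copy cells and recover the gain rate.

    Exactly ``round(gain_fraction * n_cells)`` cells carry three territory
    copies (the rest two); copies are placed along directions >= 60 degrees
    apart so same-channel blobs stay resolvable.  Returns the planted and
    recovered aneuploid-gain percentages.
    """
    rng = np.random.default_rng(seed)
    n_gain = int(round(gain_fraction * n_cells))
    copies_per_cell = np.array([3] * n_gain + [2] * (n_cells - n_gain))
    rng.shuffle(copies_per_cell)
    recovered_counts = []
    for copies in copies_per_cell:
        def territories(cell_rng, nucleus, copies=int(copies)):
            # resample placements until planted centroids sit far enough
            # apart that same-channel blobs (r ~0.9 um) cannot merge
            from .synthetic_data import surface_distance_along

            for _ in range(500):
                specs, centroids = [], []
                dirs = well_separated_directions(copies, cell_rng)
                for k in range(copies):
                    frac = float(cell_rng.uniform(0.3, 0.85))
                    t_exit = surface_distance_along(nucleus, dirs[k])
                    centroids.append(frac * t_exit * np.asarray(dirs[k]))
                    specs.append(
                        TerritorySpec("CT", frac, dirs[k], copy_index=k + 1)
                    )
                ok = all(
                    np.linalg.norm(centroids[i] - centroids[j]) >= 2.6
                    for i in range(copies)
                    for j in range(i + 1, copies)
                )
                if ok:
                    return specs
            raise RuntimeError("could not place well-separated territory copies")

        stack, _truth = _simulate_one_cell(rng, territories)
        _, objects, _ = _measure_territories(stack, "CT")
        recovered_counts.append(len(objects))
    recovered_counts = np.asarray(recovered_counts)
    return {
        "n_cells": n_cells,
        "planted_gain_pct": 100.0 * n_gain / n_cells,
        "recovered_gain_pct": 100.0 * float((recovered_counts > 2).mean()),
        "exact_copy_agreement_pct": 100.0
        * float((recovered_counts == copies_per_cell).mean()),
    }


def shell_null_calibration(
    pooled_counts=(20, 60, 80, 30, 10),
    n_replicates: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I error of the shell-distribution chi-square under the null.

    Each replicate randomly splits one pooled territory sample into two
    equal halves (a true null) and tests them against each other; the
    rejection rate at ``alpha`` should sit near the nominal level.
    """
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(5), pooled_counts)
    n = len(labels)
    half = n // 2
    rejections = 0
    from .geometry import ShellIndex

    for _ in range(n_replicates):
        perm = rng.permutation(labels)
        counts_a = np.bincount(perm[:half], minlength=5)
        counts_b = np.bincount(perm[half:], minlength=5)
        a = ShellDistribution("a", dict(zip(ShellIndex, counts_a)))
        b = ShellDistribution("b", dict(zip(ShellIndex, counts_b)))
        cmp = compare_shell_distributions(a, b)
        if cmp.chi2_p < alpha:
            rejections += 1
    return {
        "n_replicates": n_replicates,
        "rejection_rate_pct": 100.0 * rejections / n_replicates,
        "nominal_pct": 100.0 * alpha,
    }


def ks_power_experiment(
    n_per_group: int = 60,
    median_a_um: float = 0.72,
    median_b_um: float = 1.40,
    n_replicates: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Power of the two-sample KS test to detect a planted median shift in
    locus-to-lamina distances at study-scale group sizes."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        x = simulate_locus_distances(n_per_group, median_a_um, seed=int(rng.integers(2**31)))
        y = simulate_locus_distances(n_per_group, median_b_um, seed=int(rng.integers(2**31)))
        _, p = ks_two_sample(x, y)
        if p < alpha:
            hits += 1
    return {
        "n_replicates": n_replicates,
        "n_per_group": n_per_group,
        "power_pct": 100.0 * hits / n_replicates,
    }
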