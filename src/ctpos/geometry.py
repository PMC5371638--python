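"""Radial-distance, shell and lamina-distance geometry.

The central measurement is the percent radial distance of a chromosome
territory.  With A the geometric center of the nucleus and B that of the
territory, the ray from A through B is extended to the point C where it
leaves the nucleus mask; with X = |AB| and Y = |AC|,

    %RD = 100 * X / Y

so 0 is the nuclear center and 100 the periphery.  The periphery point C is
found by marching the ray in physical μm at a quarter of the smallest voxel
dimension and taking the midpoint of the last-inside / first-outside
samples (sub-voxel accurate without a rendered isosurface).

%RD values are binned into five concentric sub-shells I–V of 20 % each,
upper-inclusive: shell k covers ((k-1)*20, k*20], with 0 assigned to I —
so RD 60 falls in shell III and RD 80 in shell IV.

Gene loci are positioned by the closest Euclidean distance between the
locus center of mass and the surface of an anchor mask (the lamina
channel): surface voxels are mask voxels with at least one of their six
face neighbors outside the mask.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "RadialMeasurement",
    "ShellIndex",
    "LocusMeasurement",
    "radial_distance",
    "shell_of",
    "lamina_distance",
    "anchor_surface_voxels",
    "volumes_by_shell",
]


class ShellIndex(enum.IntEnum):
    """Concentric nuclear sub-shells, innermost (I) to peripheral (V)."""

    I = 1
    II = 2
    III = 3
    IV = 4
    V = 5


@dataclass
class RadialMeasurement:
    """The A/B/C construction for one territory."""

    A_um: tuple[float, float, float]
    B_um: tuple[float, float, float]
    C_um: tuple[float, float, float] | None
    X_um: float
    Y_um: float
    rd_percent: float
    degenerate: bool = False  # B coincided with A; C undefined


@dataclass
class LocusMeasurement:
    """Closest distance from a locus center of mass to an anchor surface."""

    cm_um: tuple[float, float, float]
    distance_um: float
    anchor_channel: str = ""


def _voxel_of(point_um, voxel_size) -> tuple[int, int, int]:
    # voxel centers sit at index * voxel_size; nearest center = round
    return tuple(int(round(point_um[i] / voxel_size[i])) for i in range(3))


def _inside(mask, idx) -> bool:
    return all(0 <= idx[i] < mask.shape[i] for i in range(3)) and bool(mask[idx])


def _in_bounds(mask, idx) -> bool:
    return all(0 <= idx[i] < mask.shape[i] for i in range(3))


def radial_distance(
    nucleus_mask: np.ndarray,
    nucleus_center_um,
    ct_center_um,
    voxel_size,
) -> RadialMeasurement:
    """%RD of a territory center B relative to nucleus center A.

    Marches the ray A->B->periphery at step 0.25 * min(voxel_size) μm; the
    periphery point C is the midpoint of the last sample inside the mask
    and the first outside it.  Degenerate B == A (within 1e-9 μm) returns
    %RD 0 with C undefined.  Errors: A outside the mask, or the ray
    leaving the image while still inside the mask (mask touches border).
    rd_percent is clamped to [0, 100] (a noisy B marginally outside the
    mask would otherwise exceed 100).
    """
    mask = np.asarray(nucleus_mask, dtype=bool)
    a = np.asarray(nucleus_center_um, dtype=float)
    b = np.asarray(ct_center_um, dtype=float)
    if not np.all(np.isfinite(b)):
        raise ValueError("territory center is not finite")
    if not _inside(mask, _voxel_of(a, voxel_size)):
        raise ValueError("nucleus center A lies outside the nucleus mask")

    x = float(np.linalg.norm(b - a))
    if x < 1e-9:
        return RadialMeasurement(
            A_um=tuple(a), B_um=tuple(b), C_um=None, X_um=0.0, Y_um=0.0,
            rd_percent=0.0, degenerate=True,
        )
    u = (b - a) / x
    step = 0.25 * min(voxel_size)
    t = 0.0
    t_inside = 0.0
    while True:
        t += step
        p = a + t * u
        idx = _voxel_of(p, voxel_size)
        if not _in_bounds(mask, idx):
            raise ValueError(
                "ray left the image bounds while still inside the mask "
                "(nucleus mask touches the image border)"
            )
        if mask[idx]:
            t_inside = t
        else:
            break
    y = 0.5 * (t_inside + t)
    c = a + y * u
    rd = min(100.0, 100.0 * x / y)
    return RadialMeasurement(
        A_um=tuple(a), B_um=tuple(b), C_um=tuple(c), X_um=x, Y_um=float(y),
        rd_percent=float(rd),
    )


def shell_of(rd_percent: float) -> ShellIndex:
    """Map %RD to its sub-shell: ((k-1)*20, k*20] -> shell k, 0 -> I."""
    if not 0.0 <= rd_percent <= 100.0:
        raise ValueError(f"rd_percent {rd_percent} outside [0, 100]")
    if rd_percent == 0.0:
        return ShellIndex.I
    return ShellIndex(int(math.ceil(rd_percent / 20.0)))


def anchor_surface_voxels(anchor_mask: np.ndarray) -> np.ndarray:
    """(n, 3) indices of mask voxels with >= 1 of 6 face neighbors outside."""
    mask = np.asarray(anchor_mask, dtype=bool)
    face = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(mask, structure=face, border_value=0)
    return np.argwhere(mask & ~interior)


def lamina_distance(
    locus_cm_um,
    anchor_mask: np.ndarray,
    voxel_size,
    anchor_channel: str = "lamina",
) -> LocusMeasurement:
    """Closest Euclidean distance (μm) from a locus CM to the anchor surface.

    The minimum runs over the physical centers of all surface voxels of the
    anchor mask; it is exactly the exhaustive-search answer.
    """
    surface = anchor_surface_voxels(anchor_mask)
    if len(surface) == 0:
        raise ValueError("anchor mask is empty")
    vox = np.asarray(voxel_size, dtype=float)
    cm = np.asarray(locus_cm_um, dtype=float)
    d2 = ((surface * vox - cm) ** 2).sum(axis=1)
    return LocusMeasurement(
        cm_um=tuple(float(v) for v in cm),
        distance_um=float(np.sqrt(d2.min())),
        anchor_channel=anchor_channel,
    )


def volumes_by_shell(
    measurements: list[tuple[RadialMeasurement, float]],
) -> dict[ShellIndex, list[float]]:
    """Group territory volumes by the sub-shell of their %RD.

    Input pairs ``(RadialMeasurement, volume_um3)``; output maps each
    occupied shell to its volume sample, ready for a Kruskal–Wallis
    comparison across shells.
    """
    groups: dict[ShellIndex, list[float]] = {}
    for rm, vol in measurements:
        groups.setdefault(shell_of(rm.rd_percent), []).append(float(vol))
    return groups
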