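"""Ground-truthed synthetic confocal stacks and expression tables.

The generator emulates the raw material of a chromosome-territory
positioning study: a DAPI-like nucleus channel (a convex ellipsoid,
optionally with a lamina rim channel), one paint channel per chromosome
containing one blob per planted territory copy, and an optional gene-locus
channel of Gaussian spots.  Every planted quantity — territory centroid,
fractional radial position, copy number, volume — is recorded in a
:class:`GroundTruth` sidecar so downstream segmentation and geometry can be
validated against known truth.

All placement math is done in physical μm; rasterization onto the
anisotropic voxel grid happens last.  Image formation is a Gaussian PSF
blur followed by Poisson shot noise and additive Gaussian read noise,
quantized to the acquisition bit depth.  Identical seeds give bit-identical
stacks.

Expression-side simulation plants an exact number of deregulated genes per
chromosome (``round(fraction/100 * coding_genes)`` pass the |FC| >= 2,
p < 0.05 filter; every other gene fails it), and a paired-knockdown helper
plants a known overlap between two deregulated gene sets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial.transform import Rotation

from .expression import GeneRecord
from .imaging_io import DEFAULT_VOXEL_SIZE_UM, StackSet, VoxelImage

__all__ = [
    "NucleusSpec",
    "TerritorySpec",
    "LocusSpec",
    "AcquisitionSpec",
    "GroundTruth",
    "simulate_cell",
    "centered_nucleus",
    "ChromosomeSimSpec",
    "ExpressionSimSpec",
    "simulate_expression_table",
    "simulate_knockdown_pair",
    "simulate_locus_distances",
    "CohortChromosome",
    "CohortSpec",
    "simulate_cohort",
    "well_separated_directions",
]


# --------------------------------------------------------------------------
# specs


@dataclass
class NucleusSpec:
    """Ellipsoidal nucleus: center and semi-axes in μm (z, y, x order),
    orientation as intrinsic x-y-z Euler angles in radians."""

    center_um: tuple[float, float, float]
    semi_axes_um: tuple[float, float, float]
    orientation_rad: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.center_um = tuple(float(v) for v in self.center_um)
        self.semi_axes_um = tuple(float(v) for v in self.semi_axes_um)
        self.orientation_rad = tuple(float(v) for v in self.orientation_rad)
        if any(a <= 0 for a in self.semi_axes_um):
            raise ValueError(f"semi-axes must be positive, got {self.semi_axes_um}")

    @property
    def volume_um3(self) -> float:
        az, ay, ax = self.semi_axes_um
        return 4.0 / 3.0 * math.pi * az * ay * ax

    def rotation(self) -> np.ndarray:
        """3x3 matrix rotating body-frame (z,y,x) vectors into the world frame."""
        r_xyz = Rotation.from_euler("xyz", self.orientation_rad).as_matrix()
        return r_xyz[::-1, ::-1].copy()  # conjugate by axis reversal: acts on zyx

    def bounding_half_extents(self) -> np.ndarray:
        """Half-widths of the axis-aligned bounding box of the rotated ellipsoid."""
        m = self.rotation()
        a = np.asarray(self.semi_axes_um)
        return np.sqrt(((m * a) ** 2).sum(axis=1))


@dataclass
class TerritorySpec:
    """One planted chromosome-territory copy.

    ``fractional_rd`` is the planted ground-truth radial position: the
    territory centroid is placed at ``fractional_rd`` times the
    center-to-surface distance along ``direction`` (unit vector, z,y,x).
    The number of TerritorySpec entries sharing a ``chromosome_label``
    defines the planted copy number of that chromosome.
    """

    chromosome_label: str
    fractional_rd: float
    direction: tuple[float, float, float]
    target_volume_um3: float = 3.0
    copy_index: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.fractional_rd <= 1.0:
            raise ValueError(
                f"{self.chromosome_label}: fractional_rd {self.fractional_rd} "
                "outside [0, 1] places the territory outside the nucleus"
            )
        if self.target_volume_um3 <= 0:
            raise ValueError(f"{self.chromosome_label}: target_volume must be > 0")
        if self.copy_index < 1:
            raise ValueError(f"{self.chromosome_label}: copy_index must be >= 1")
        d = np.asarray(self.direction, dtype=float)
        n = float(np.linalg.norm(d))
        if n == 0:
            raise ValueError(f"{self.chromosome_label}: zero direction vector")
        self.direction = tuple(d / n)


@dataclass
class LocusSpec:
    """A gene-locus spot: Gaussian of width sigma at a fixed μm position."""

    name: str
    position_um: tuple[float, float, float]
    sigma_um: float = 0.25
    amplitude: float = 1.0


@dataclass
class AcquisitionSpec:
    """Imaging model: calibration, PSF, noise and quantization.

    Defaults mirror a 63x/1.4 NA confocal acquisition at 0.105 x 0.105 x
    0.34 μm voxels with 8-bit channels.  ``photon_scale`` is the expected
    photon count inside an object; set ``shot_noise=False`` and
    ``read_noise_sd=0`` for a deterministic, noiseless rendering.
    """

    voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM
    psf_sigma_um: tuple[float, float, float] = (0.25, 0.1, 0.1)
    photon_scale: float = 180.0
    read_noise_sd: float = 2.0
    bit_depth: int = 8
    shot_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError(f"voxel size must be positive: {self.voxel_size_um}")
        if any(s < 0 for s in self.psf_sigma_um):
            raise ValueError(f"psf sigma must be >= 0: {self.psf_sigma_um}")
        if self.photon_scale <= 0:
            raise ValueError("photon_scale must be > 0")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def dtype(self):
        return np.uint8 if self.bit_depth == 8 else np.uint16

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1


# --------------------------------------------------------------------------
# geometry helpers (placement in μm, rasterization last)


def _grid_um(shape, voxel_size):
    vz, vy, vx = voxel_size
    z = np.arange(shape[0]) * vz
    y = np.arange(shape[1]) * vy
    x = np.arange(shape[2]) * vx
    return np.meshgrid(z, y, x, indexing="ij")


def _ellipsoid_mask(shape, voxel_size, center, semi_axes, rot) -> np.ndarray:
    zz, yy, xx = _grid_um(shape, voxel_size)
    d = np.stack([zz - center[0], yy - center[1], xx - center[2]])
    # body coords: q = R^T d
    q = np.einsum("ji,jzyx->izyx", rot, d)
    a = np.asarray(semi_axes).reshape(3, 1, 1, 1)
    return ((q / a) ** 2).sum(axis=0) <= 1.0


def surface_distance_along(nucleus: NucleusSpec, direction) -> float:
    """Center-to-surface distance of the nucleus ellipsoid along a unit
    direction (z,y,x) — closed form."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    w = nucleus.rotation().T @ d / np.asarray(nucleus.semi_axes_um)
    return float(1.0 / np.linalg.norm(w))


def _sphere_mask_subvolume(shape, voxel_size, center, radius):
    """Boolean sphere raster restricted to its bounding sub-box.

    Returns (slices, submask) so callers can paste into a full-size array.
    """
    vz, vy, vx = voxel_size
    lo = [max(0, int(math.floor((center[i] - radius) / voxel_size[i])) - 1) for i in range(3)]
    hi = [
        min(shape[i], int(math.ceil((center[i] + radius) / voxel_size[i])) + 2)
        for i in range(3)
    ]
    sl = tuple(slice(lo[i], hi[i]) for i in range(3))
    z = np.arange(lo[0], hi[0]) * vz
    y = np.arange(lo[1], hi[1]) * vy
    x = np.arange(lo[2], hi[2]) * vx
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
    d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    return sl, d2 <= radius**2


def _render_territory_blob(shape, voxel_size, center, target_volume, tol=0.02):
    """Rasterize a spherical blob, tuning the radius so the voxelized volume
    hits ``target_volume`` within ``tol`` (relative)."""
    voxvol = float(np.prod(voxel_size))
    r = (3.0 * target_volume / (4.0 * math.pi)) ** (1.0 / 3.0)
    best = None
    for _ in range(20):
        sl, sub = _sphere_mask_subvolume(shape, voxel_size, center, r)
        count = int(sub.sum())
        if count == 0:
            r *= 1.3
            continue
        vol = count * voxvol
        err = abs(vol - target_volume) / target_volume
        if best is None or err < best[0]:
            best = (err, sl, sub, vol)
        if err <= tol:
            break
        r *= (target_volume / vol) ** (1.0 / 3.0)
    if best is None:
        raise ValueError("territory blob renders to zero voxels at this calibration")
    return best[1], best[2], best[3]


def place_separated_territories(
    nucleus: NucleusSpec,
    label: str,
    copies: int,
    rd_low: float,
    rd_high: float,
    target_volume_um3: float,
    rng: np.random.Generator,
    min_separation_um: float | None = None,
    max_tries: int = 200,
) -> list[TerritorySpec]:
    """Sample ``copies`` territory placements whose planted centroids keep a
    physical separation so same-channel blobs stay resolvable.

    Default separation: blob diameter plus 0.7 μm of clearance.  If the
    nucleus is too small to honour it, the best-separated attempt is used
    (copies may then merge downstream — exactly what happens with closely
    apposed homologs in real nuclei).
    """
    r_blob = (3.0 * target_volume_um3 / (4.0 * math.pi)) ** (1.0 / 3.0)
    if min_separation_um is None:
        min_separation_um = 2.0 * r_blob + 0.7
    best: tuple[float, list[TerritorySpec]] | None = None
    for _ in range(max_tries):
        dirs = well_separated_directions(copies, rng, min_angle_deg=40.0)
        specs, centroids = [], []
        for k in range(copies):
            frac = float(rng.uniform(rd_low, rd_high))
            t_exit = surface_distance_along(nucleus, dirs[k])
            centroids.append(frac * t_exit * np.asarray(dirs[k]))
            specs.append(
                TerritorySpec(label, frac, dirs[k], target_volume_um3, copy_index=k + 1)
            )
        sep = min(
            (
                float(np.linalg.norm(centroids[i] - centroids[j]))
                for i in range(copies)
                for j in range(i + 1, copies)
            ),
            default=math.inf,
        )
        if sep >= min_separation_um:
            return specs
        if best is None or sep > best[0]:
            best = (sep, specs)
    return best[1]


def well_separated_directions(n: int, rng: np.random.Generator, min_angle_deg: float = 60.0):
    """Draw ``n`` random unit vectors (z,y,x) pairwise separated by at least
    ``min_angle_deg`` (rejection sampling)."""
    cos_max = math.cos(math.radians(min_angle_deg))
    dirs: list[np.ndarray] = []
    for _ in range(10_000):
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        if all(abs(float(v @ u)) <= 1 and float(v @ u) < cos_max for u in dirs):
            dirs.append(v)
            if len(dirs) == n:
                return [tuple(d) for d in dirs]
    raise RuntimeError(f"could not place {n} directions {min_angle_deg} deg apart")


# --------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    """Everything that was planted in one synthetic cell."""

    seed: int
    voxel_size_um: tuple[float, float, float]
    shape: tuple[int, int, int]
    nucleus: dict
    territories: list[dict] = field(default_factory=list)
    loci: list[dict] = field(default_factory=list)
    lamina_thickness_um: float | None = None

    @property
    def copy_number(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for t in self.territories:
            counts[t["chromosome"]] = counts.get(t["chromosome"], 0) + 1
        return counts

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "voxel_size_um": list(self.voxel_size_um),
            "shape": list(self.shape),
            "nucleus": self.nucleus,
            "territories": self.territories,
            "loci": self.loci,
            "lamina_thickness_um": self.lamina_thickness_um,
            "copy_number": self.copy_number,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# --------------------------------------------------------------------------
# cell simulation


def centered_nucleus(
    semi_axes_um,
    acq: AcquisitionSpec,
    pad_um: float = 1.5,
    orientation_rad=(0.0, 0.0, 0.0),
) -> tuple[NucleusSpec, tuple[int, int, int]]:
    """Build a NucleusSpec centered in an auto-sized field.

    The field leaves ``pad_um`` of clearance around the rotated ellipsoid's
    bounding box on every side (must exceed the 2-voxel margin the renderer
    enforces).
    """
    nuc = NucleusSpec((0, 0, 0), semi_axes_um, orientation_rad)
    h = nuc.bounding_half_extents()
    vox = np.asarray(acq.voxel_size_um)
    center = h + pad_um
    shape = tuple(int(math.ceil((2 * (h[i] + pad_um)) / vox[i])) + 1 for i in range(3))
    return NucleusSpec(tuple(center), semi_axes_um, orientation_rad), shape


def simulate_cell(
    nucleus: NucleusSpec,
    territories: list[TerritorySpec],
    acq: AcquisitionSpec,
    lamina_thickness_um: float | None = None,
    loci: list[LocusSpec] = (),
    shape: tuple[int, int, int] | None = None,
) -> tuple[StackSet, GroundTruth]:
    """Render one synthetic cell as a multi-channel stack plus ground truth.

    Channels: ``"dapi"`` (nucleus body), one channel per distinct
    ``chromosome_label`` (all copies of that chromosome), optionally
    ``"lamina"`` (a rim of the given thickness at the nucleus boundary) and
    ``"locus"`` (Gaussian spots).  Overlapping same-channel territory blobs
    are allowed but flagged in the ground truth.
    """
    vox = np.asarray(acq.voxel_size_um)
    if shape is None:
        h = nucleus.bounding_half_extents()
        c = np.asarray(nucleus.center_um)
        shape = tuple(int(math.ceil((c[i] + h[i] + 2 * vox[i]) / vox[i])) + 1 for i in range(3))
    shape = tuple(int(s) for s in shape)

    # nucleus must fit with >= 2-voxel margin on every side
    h = nucleus.bounding_half_extents()
    c = np.asarray(nucleus.center_um)
    extent = (np.asarray(shape) - 1) * vox
    if np.any(c - h < 2 * vox) or np.any(extent - (c + h) < 2 * vox):
        raise ValueError(
            "nucleus does not fit inside the image bounds with a 2-voxel margin"
        )

    rot = nucleus.rotation()
    truth = GroundTruth(
        seed=acq.seed,
        voxel_size_um=tuple(vox),
        shape=shape,
        nucleus={
            "center_um": list(nucleus.center_um),
            "semi_axes_um": list(nucleus.semi_axes_um),
            "orientation_rad": list(nucleus.orientation_rad),
            "volume_um3": nucleus.volume_um3,
        },
        lamina_thickness_um=lamina_thickness_um,
    )

    fields: dict[str, np.ndarray] = {}
    nucleus_mask = _ellipsoid_mask(shape, vox, nucleus.center_um, nucleus.semi_axes_um, rot)
    fields["dapi"] = nucleus_mask.astype(np.float64)

    # territories grouped into one channel per chromosome label
    blobs: dict[str, list[tuple[TerritorySpec, tuple, np.ndarray]]] = {}
    for spec in territories:
        t_exit = surface_distance_along(nucleus, spec.direction)
        centroid = np.asarray(nucleus.center_um) + spec.fractional_rd * t_exit * np.asarray(
            spec.direction
        )
        sl, sub, rendered_vol = _render_territory_blob(
            shape, vox, centroid, spec.target_volume_um3
        )
        ch = fields.setdefault(spec.chromosome_label, np.zeros(shape))
        ch[sl] = np.maximum(ch[sl], sub.astype(np.float64))
        blobs.setdefault(spec.chromosome_label, []).append((spec, sl, sub))
        truth.territories.append(
            {
                "chromosome": spec.chromosome_label,
                "copy_index": spec.copy_index,
                "centroid_um": [float(v) for v in centroid],
                "fractional_rd": spec.fractional_rd,
                "planted_rd_percent": 100.0 * spec.fractional_rd,
                "direction": [float(v) for v in spec.direction],
                "target_volume_um3": spec.target_volume_um3,
                "rendered_volume_um3": rendered_vol,
                "overlaps": [],
            }
        )

    # flag overlapping same-channel blobs
    by_channel: dict[str, list[int]] = {}
    for idx, t in enumerate(truth.territories):
        by_channel.setdefault(t["chromosome"], []).append(idx)
    for label, indices in by_channel.items():
        entries = blobs[label]
        for i in range(len(entries)):
            for j in range(i + 1, len(entries)):
                if _blobs_overlap(entries[i][1:], entries[j][1:], shape):
                    ci = truth.territories[indices[i]]["copy_index"]
                    cj = truth.territories[indices[j]]["copy_index"]
                    truth.territories[indices[i]]["overlaps"].append(cj)
                    truth.territories[indices[j]]["overlaps"].append(ci)

    if lamina_thickness_um is not None:
        inner_axes = np.asarray(nucleus.semi_axes_um) - lamina_thickness_um
        if np.any(inner_axes <= 0):
            raise ValueError("lamina thickness exceeds a nucleus semi-axis")
        inner = _ellipsoid_mask(shape, vox, nucleus.center_um, inner_axes, rot)
        fields["lamina"] = (nucleus_mask & ~inner).astype(np.float64)

    if loci:
        locus_field = np.zeros(shape)
        zz, yy, xx = _grid_um(shape, vox)
        for spot in loci:
            d2 = (
                (zz - spot.position_um[0]) ** 2
                + (yy - spot.position_um[1]) ** 2
                + (xx - spot.position_um[2]) ** 2
            )
            locus_field += spot.amplitude * np.exp(-0.5 * d2 / spot.sigma_um**2)
            truth.loci.append(
                {
                    "name": spot.name,
                    "position_um": [float(v) for v in spot.position_um],
                    "sigma_um": spot.sigma_um,
                }
            )
        fields["locus"] = locus_field

    rng = np.random.default_rng(acq.seed)
    channels = {
        name: VoxelImage(_acquire(f, acq, rng), tuple(vox), channel_name=name)
        for name, f in fields.items()
    }
    return StackSet(channels), truth


def _blobs_overlap(a, b, shape) -> bool:
    sl_a, sub_a = a
    sl_b, sub_b = b
    lo = [max(sl_a[i].start, sl_b[i].start) for i in range(3)]
    hi = [min(sl_a[i].stop, sl_b[i].stop) for i in range(3)]
    if any(lo[i] >= hi[i] for i in range(3)):
        return False
    cut_a = tuple(slice(lo[i] - sl_a[i].start, hi[i] - sl_a[i].start) for i in range(3))
    cut_b = tuple(slice(lo[i] - sl_b[i].start, hi[i] - sl_b[i].start) for i in range(3))
    return bool(np.any(sub_a[cut_a] & sub_b[cut_b]))


def _acquire(signal: np.ndarray, acq: AcquisitionSpec, rng: np.random.Generator) -> np.ndarray:
    """PSF blur -> shot noise -> read noise -> quantize."""
    sigma_vox = np.asarray(acq.psf_sigma_um) / np.asarray(acq.voxel_size_um)
    if np.any(sigma_vox > 0):
        signal = gaussian_filter(signal, sigma=sigma_vox)
    expected = acq.photon_scale * np.clip(signal, 0.0, None)
    if acq.shot_noise:
        counts = rng.poisson(expected).astype(np.float64)
    else:
        counts = expected
    if acq.read_noise_sd > 0:
        counts = counts + rng.normal(0.0, acq.read_noise_sd, size=counts.shape)
    return np.clip(np.rint(counts), 0, acq.max_value).astype(acq.dtype)


# --------------------------------------------------------------------------
# cohort simulation


@dataclass
class CohortChromosome:
    """Population-level description of one painted chromosome.

    ``rd_low``/``rd_high`` bound the uniform distribution of planted
    fractional radial positions; ``gain_fraction``/``loss_fraction`` give
    the probability that a cell carries three (resp. one) copies instead of
    the diploid two.
    """

    label: str
    rd_low: float = 0.3
    rd_high: float = 0.9
    gain_fraction: float = 0.0
    loss_fraction: float = 0.0
    target_volume_um3: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rd_low <= self.rd_high <= 1.0:
            raise ValueError(f"{self.label}: bad rd range [{self.rd_low}, {self.rd_high}]")
        if self.gain_fraction + self.loss_fraction > 1.0:
            raise ValueError(f"{self.label}: gain + loss fractions exceed 1")


@dataclass
class CohortSpec:
    """A condition's worth of synthetic cells."""

    n_cells: int
    chromosomes: list[CohortChromosome]
    acq: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    semi_axes_um: tuple[float, float, float] = (3.2, 5.5, 5.0)
    semi_axes_jitter: float = 0.08
    lamina_thickness_um: float | None = None
    pad_um: float = 1.5
    seed: int = 0


def simulate_cohort(spec: CohortSpec):
    """Yield ``(cell_id, StackSet, GroundTruth)`` for each cell of a cohort.

    Per-cell randomness (nucleus size/orientation, copy number, radial
    positions, directions, acquisition noise) derives deterministically from
    ``spec.seed``.
    """
    master = np.random.default_rng(spec.seed)
    for i in range(spec.n_cells):
        cell_seed = int(master.integers(2**31))
        rng = np.random.default_rng(cell_seed)
        axes = tuple(
            a * (1.0 + rng.uniform(-spec.semi_axes_jitter, spec.semi_axes_jitter))
            for a in spec.semi_axes_um
        )
        orientation = tuple(rng.uniform(0, 2 * math.pi, size=3))
        acq = AcquisitionSpec(
            voxel_size_um=spec.acq.voxel_size_um,
            psf_sigma_um=spec.acq.psf_sigma_um,
            photon_scale=spec.acq.photon_scale,
            read_noise_sd=spec.acq.read_noise_sd,
            bit_depth=spec.acq.bit_depth,
            shot_noise=spec.acq.shot_noise,
            seed=cell_seed,
        )
        nucleus, shape = centered_nucleus(axes, acq, pad_um=spec.pad_um, orientation_rad=orientation)
        territories = []
        for chrom in spec.chromosomes:
            u = rng.uniform()
            if u < chrom.gain_fraction:
                copies = 3
            elif u < chrom.gain_fraction + chrom.loss_fraction:
                copies = 1
            else:
                copies = 2
            territories.extend(
                place_separated_territories(
                    nucleus,
                    chrom.label,
                    copies,
                    chrom.rd_low,
                    chrom.rd_high,
                    chrom.target_volume_um3,
                    rng,
                )
            )
        stack, truth = simulate_cell(
            nucleus,
            territories,
            acq,
            lamina_thickness_um=spec.lamina_thickness_um,
            shape=shape,
        )
        yield f"cell{i:04d}", stack, truth


# --------------------------------------------------------------------------
# expression simulation


@dataclass
class ChromosomeSimSpec:
    """Planted deregulation for one chromosome."""

    label: str
    coding_genes: int
    length_mbp: float
    dereg_fraction_pct: float = 0.0

    def __post_init__(self) -> None:
        if self.coding_genes <= 0:
            raise ValueError(f"{self.label}: coding_genes must be > 0")
        if self.length_mbp <= 0:
            raise ValueError(f"{self.label}: length_mbp must be > 0")
        if self.dereg_fraction_pct < 0:
            raise ValueError(f"{self.label}: negative deregulation fraction")
        if self.dereg_fraction_pct > 100:
            raise ValueError(
                f"{self.label}: planted deregulation fraction "
                f"{self.dereg_fraction_pct} % exceeds 100 %"
            )

    @property
    def gene_density(self) -> float:
        return self.coding_genes / self.length_mbp


@dataclass
class ExpressionSimSpec:
    """Expression-table simulation: per-chromosome planted fractions plus
    fold-change/p-value distributions for deregulated and null genes."""

    chromosomes: list[ChromosomeSimSpec]
    dereg_fc_scale: float = 1.0  # |fc| = 2 + Exponential(scale)
    null_fc_range: tuple[float, float] = (1.05, 1.85)
    seed: int = 0


def _gene_universe(chromosomes) -> dict[str, list[str]]:
    return {
        c.label: [f"{c.label}_g{i:05d}" for i in range(c.coding_genes)]
        for c in chromosomes
    }


def _emit_records(
    chromosomes, dereg_sign: dict[str, int], spec: ExpressionSimSpec, rng
) -> list[GeneRecord]:
    lo, hi = spec.null_fc_range
    records = []
    for chrom in chromosomes:
        for gid in _gene_universe([chrom])[chrom.label]:
            sign = dereg_sign.get(gid)
            if sign is not None:
                fc = sign * (2.0 + rng.exponential(spec.dereg_fc_scale))
                p = float(rng.uniform(1e-6, 0.05))  # < 0.05 strictly
            else:
                fc = float(rng.choice([-1, 1])) * float(rng.uniform(lo, hi))
                p = float(rng.uniform(0.0, 1.0))
            records.append(
                GeneRecord(gene_id=gid, chromosome=chrom.label, fold_change=float(fc), p_value=p)
            )
    return records


def simulate_expression_table(spec: ExpressionSimSpec) -> tuple[list[GeneRecord], dict]:
    """Emit a gene table with exact planted per-chromosome deregulation.

    Per chromosome, exactly ``round(fraction/100 * coding_genes)`` genes pass
    the |FC| >= 2, p < 0.05 filter; all others fail the fold-change cutoff.
    Returns the records plus a truth dict with the planted deregulated ids.
    """
    rng = np.random.default_rng(spec.seed)
    dereg_sign: dict[str, int] = {}
    per_chrom: dict[str, int] = {}
    for chrom in spec.chromosomes:
        n_dereg = int(round(chrom.dereg_fraction_pct / 100.0 * chrom.coding_genes))
        per_chrom[chrom.label] = n_dereg
        ids = _gene_universe([chrom])[chrom.label]
        chosen = rng.choice(len(ids), size=n_dereg, replace=False)
        for idx in chosen:
            dereg_sign[ids[int(idx)]] = int(rng.choice([-1, 1]))
    records = _emit_records(spec.chromosomes, dereg_sign, spec, rng)
    truth = {
        "dereg_ids": set(dereg_sign),
        "per_chromosome_n_dereg": per_chrom,
        "signs": dict(dereg_sign),
    }
    return records, truth


def simulate_knockdown_pair(
    chromosomes: list[ChromosomeSimSpec],
    n_up_a: int,
    n_down_a: int,
    n_up_b: int,
    n_down_b: int,
    n_common: int,
    seed: int = 0,
    fc_spec: ExpressionSimSpec | None = None,
) -> tuple[list[GeneRecord], list[GeneRecord], dict]:
    """Two knockdown tables over one gene universe with a planted overlap.

    Condition A deregulates ``n_up_a + n_down_a`` genes, condition B
    ``n_up_b + n_down_b``; exactly ``n_common`` gene ids are deregulated in
    both.  Signs are assigned independently per condition.
    """
    total_a = n_up_a + n_down_a
    total_b = n_up_b + n_down_b
    if n_common > min(total_a, total_b):
        raise ValueError("n_common exceeds a condition's deregulated total")
    universe = [g for c in chromosomes for g in _gene_universe([c])[c.label]]
    needed = total_a + total_b - n_common
    if needed > len(universe):
        raise ValueError("gene universe too small for requested deregulated sets")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(universe), size=needed, replace=False)
    ids = [universe[int(i)] for i in picks]
    common = ids[:n_common]
    only_a = ids[n_common : n_common + (total_a - n_common)]
    only_b = ids[n_common + (total_a - n_common) :]
    set_a = common + only_a
    set_b = common + only_b

    def signed(id_list, n_up):
        order = rng.permutation(len(id_list))
        signs = {}
        for rank, idx in enumerate(order):
            signs[id_list[int(idx)]] = 1 if rank < n_up else -1
        return signs

    base = fc_spec or ExpressionSimSpec(chromosomes=chromosomes)
    records_a = _emit_records(chromosomes, signed(set_a, n_up_a), base, rng)
    records_b = _emit_records(chromosomes, signed(set_b, n_up_b), base, rng)
    truth = {
        "dereg_ids_a": set(set_a),
        "dereg_ids_b": set(set_b),
        "common_ids": set(common),
    }
    return records_a, records_b, truth


def simulate_locus_distances(
    n: int, median_um: float, sigma_log: float = 0.55, seed: int = 0
) -> np.ndarray:
    """Locus-to-lamina distances (μm) as a lognormal with the given median.

    Emulates the skewed, non-negative distance distributions seen for a
    single-gene locus against the lamina reference surface.
    """
    rng = np.random.default_rng(seed)
    return np.exp(rng.normal(math.log(median_um), sigma_log, size=n))
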