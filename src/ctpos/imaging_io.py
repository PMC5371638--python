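"""Calibrated stack and table I/O.

All geometry in this package is done in physical micrometres on anisotropic
voxel grids, so every image that enters the pipeline is wrapped in a
:class:`VoxelImage` that carries its voxel dimensions.  Multi-channel z-stacks
are grouped into a :class:`StackSet` whose channels share one calibration.

Axis convention (fixed package-wide): arrays are indexed ``(Z, Y, X)``,
voxel indices are 0-based, and the physical coordinate of voxel ``(k, j, i)``
is ``(k*vz, j*vy, i*vx)`` μm — i.e. physical coordinates are voxel centers.

TIFF files are written as ImageJ-style hyperstacks with the voxel size
recorded in the resolution tags (XY) and ImageJ ``spacing`` (Z); channel
names travel in the ImageJ ``Info`` field as JSON.  OME-XML pixel sizes are
honoured on read when present.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "VoxelImage",
    "StackSet",
    "read_stack",
    "write_stack",
    "read_gene_table",
    "read_annotation",
    "canonical_chromosome",
    "CANONICAL_CHROMOSOMES",
    "DEFAULT_VOXEL_SIZE_UM",
]

#: Confocal calibration used throughout as the default: (z, y, x) μm.
DEFAULT_VOXEL_SIZE_UM = (0.34, 0.105, 0.105)

CANONICAL_CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X", "Y")


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


def canonical_chromosome(label: object) -> str:
    """Normalize a chromosome label to the canonical set 1–22, X, Y.

    Accepts e.g. ``"chr19"``, ``"19"``, ``19``, ``"x"``.
    """
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    s = s.upper()
    if s not in CANONICAL_CHROMOSOMES:
        raise FormatError(f"unrecognized chromosome label: {label!r}")
    return s


@dataclass
class VoxelImage:
    """One channel of a 3D stack with physical voxel dimensions.

    Parameters
    ----------
    intensities:
        ``(Z, Y, X)`` array of non-negative integers.
    voxel_size:
        ``(z, y, x)`` voxel edge lengths in μm.
    channel_name:
        Free-text channel identifier (e.g. ``"dapi"``, ``"CT19"``).
    """

    intensities: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise FormatError(
                f"channel {self.channel_name!r}: expected 3D (Z,Y,X) data, "
                f"got {self.intensities.ndim}D"
            )
        if any(s < 2 for s in self.intensities.shape):
            raise FormatError(
                f"channel {self.channel_name!r}: each axis needs >= 2 voxels, "
                f"got shape {self.intensities.shape}"
            )
        if not np.issubdtype(self.intensities.dtype, np.integer):
            raise FormatError(
                f"channel {self.channel_name!r}: intensities must be integers, "
                f"got dtype {self.intensities.dtype}"
            )
        if self.intensities.min() < 0:
            raise FormatError(f"channel {self.channel_name!r}: negative intensities")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise FormatError(f"invalid voxel size {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_size))


@dataclass
class StackSet:
    """Ordered set of channels sharing shape and calibration."""

    channels: dict[str, VoxelImage] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise FormatError("StackSet needs at least one channel")
        shapes = {c.shape for c in self.channels.values()}
        sizes = {c.voxel_size for c in self.channels.values()}
        if len(shapes) != 1 or len(sizes) != 1:
            raise FormatError(
                f"channels disagree in shape {shapes} or calibration {sizes}"
            )

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return next(iter(self.channels.values())).voxel_size

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def names(self) -> list[str]:
        return list(self.channels)

    def __getitem__(self, name: str) -> VoxelImage:
        return self.channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.channels


def write_stack(stacks: StackSet, path) -> None:
    """Write a StackSet as an ImageJ-style multi-channel TIFF hyperstack.

    Integer dtype (8- or 16-bit) and calibration survive a round trip
    through :func:`read_stack`.
    """
    if not isinstance(stacks, StackSet):
        raise FormatError("write_stack expects a StackSet")
    vz, vy, vx = stacks.voxel_size
    data = np.stack([stacks[name].intensities for name in stacks.names], axis=1)
    # ImageJ hyperstack axis order: (Z, C, Y, X)
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(1.0 / vx, 1.0 / vy),
        metadata={
            "spacing": vz,
            "unit": "um",
            "axes": "ZCYX",
            "Info": json.dumps({"channel_names": stacks.names}),
        },
    )


def _voxel_size_from_tiff(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    """Extract (z, y, x) μm voxel size from ImageJ tags or OME-XML, if present."""
    if tif.ome_metadata:
        import re

        m = re.search(r'PhysicalSizeX="([\d.eE+-]+)"', tif.ome_metadata)
        my = re.search(r'PhysicalSizeY="([\d.eE+-]+)"', tif.ome_metadata)
        mz = re.search(r'PhysicalSizeZ="([\d.eE+-]+)"', tif.ome_metadata)
        if m and my and mz:
            return (float(mz.group(1)), float(my.group(1)), float(m.group(1)))
    ij = tif.imagej_metadata or {}
    spacing = ij.get("spacing")
    page = tif.pages[0]
    xres = page.tags.get("XResolution")
    yres = page.tags.get("YResolution")
    if spacing is not None and xres is not None and yres is not None:
        xr = xres.value[0] / xres.value[1]
        yr = yres.value[0] / yres.value[1]
        if xr > 0 and yr > 0:
            return (float(spacing), 1.0 / yr, 1.0 / xr)
    return None


def read_stack(path, default_voxel_size: tuple[float, float, float] | None = None) -> StackSet:
    """Read a TIFF hyperstack into a calibrated StackSet.

    If the file carries no voxel-size metadata, ``default_voxel_size``
    (``(z, y, x)`` μm) is applied with a warning; without a default this is
    an error, because uncalibrated geometry would be meaningless downstream.
    """
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes
        voxel_size = _voxel_size_from_tiff(tif)
        ij = tif.imagej_metadata or {}
    names: list[str] | None = None
    info = ij.get("Info")
    if info:
        try:
            names = json.loads(info).get("channel_names")
        except (json.JSONDecodeError, AttributeError):
            names = None

    # Normalize to (C, Z, Y, X)
    axes = axes.replace("S", "")
    if data.ndim == 2:
        raise FormatError(f"{path}: 2D image; a 3D z-stack is required")
    if data.ndim == 3:
        # a plain stack of pages with no axis metadata is a z-stack here;
        # tifffile may guess the page axis as Q or C
        axes = "ZYX" if "Z" not in axes else axes
        data = data[np.newaxis]
        axes = "C" + axes
    axes = axes.replace("Q", "C")
    if data.ndim != 4 or sorted(axes) != ["C", "X", "Y", "Z"]:
        raise FormatError(f"{path}: unsupported TIFF layout (axes {axes!r}, shape {data.shape})")
    order = [axes.index(a) for a in "CZYX"]
    data = np.transpose(data, order)

    if voxel_size is None:
        if default_voxel_size is None:
            raise FormatError(
                f"{path}: no voxel-size metadata and no default calibration given"
            )
        warnings.warn(
            f"{path}: no voxel-size metadata; applying default {default_voxel_size} um",
            stacklevel=2,
        )
        voxel_size = tuple(float(v) for v in default_voxel_size)

    if names is None or len(names) != data.shape[0]:
        names = [f"ch{i}" for i in range(data.shape[0])]
    channels = {
        name: VoxelImage(data[i], voxel_size, channel_name=name)
        for i, name in enumerate(names)
    }
    return StackSet(channels)


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # noqa: BLE001 - surface as format error
        raise FormatError(f"{path}: cannot parse TSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def _to_float(value: str, column: str, row: int, path) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise FormatError(
            f"{path}: row {row}: non-numeric {column} value {value!r}"
        ) from None


def read_gene_table(path) -> list:
    """Read a per-gene expression TSV into typed :class:`~ctpos.expression.GeneRecord` rows.

    Required header: ``gene_id  chromosome  fold_change  p_value``.
    Chromosome labels are canonicalized; parse errors name the offending row
    (1-based, excluding the header).
    """
    from .expression import GeneRecord

    df = _read_tsv(path, ["gene_id", "chromosome", "fold_change", "p_value"])
    records = []
    for row, rec in enumerate(df.itertuples(index=False), start=1):
        records.append(
            GeneRecord(
                gene_id=str(rec.gene_id),
                chromosome=canonical_chromosome(rec.chromosome),
                fold_change=_to_float(rec.fold_change, "fold_change", row, path),
                p_value=_to_float(rec.p_value, "p_value", row, path),
            )
        )
    return records


def read_annotation(path) -> list:
    """Read a chromosome annotation TSV into :class:`~ctpos.expression.ChromosomeAnnotation` rows.

    Required header: ``chromosome  coding_genes  length_mbp``.
    """
    from .expression import ChromosomeAnnotation

    df = _read_tsv(path, ["chromosome", "coding_genes", "length_mbp"])
    rows = []
    for row, rec in enumerate(df.itertuples(index=False), start=1):
        coding = _to_float(rec.coding_genes, "coding_genes", row, path)
        rows.append(
            ChromosomeAnnotation(
                chromosome=canonical_chromosome(rec.chromosome),
                coding_genes=int(coding),
                length_mbp=_to_float(rec.length_mbp, "length_mbp", row, path),
            )
        )
    return rows
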