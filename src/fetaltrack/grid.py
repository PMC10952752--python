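"""Grid geometry, world/voxel coordinate conventions, NIfTI I/O and fixed-grid
preprocessing.

Coordinate conventions
----------------------
All world coordinates are in millimetres.  The package-wide axis convention is
x: right -> left, y: bottom -> top, z: front -> back of the scanner bore.
Voxel indices are 0-based; the continuous grid "center" is the midpoint index
``(shape - 1) / 2`` per axis, so even-sized grids have a half-voxel-offset
center.  A :class:`GridGeometry` maps the midpoint index exactly onto its
``fov_center``::

    world = fov_center + spacing * (index - (shape - 1) / 2)

NIfTI files are written with a diagonal affine (``diag(spacing)``) whose
translation places the grid midpoint at ``fov_center``; 4D files are read as a
repetition series.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import NamedTuple, Sequence, Union

import nibabel as nib
import numpy as np
from scipy import ndimage


class WorldPoint(NamedTuple):
    """A point in scanner (world) coordinates, in millimetres."""

    x: float
    y: float
    z: float

    @staticmethod
    def from_array(a: Sequence[float]) -> "WorldPoint":
        a = np.asarray(a, dtype=float)
        if a.shape != (3,) or not np.all(np.isfinite(a)):
            raise ValueError("world point must be 3 finite coordinates")
        return WorldPoint(float(a[0]), float(a[1]), float(a[2]))

    def to_array(self) -> np.ndarray:
        return np.array(self, dtype=float)


def _as_triple(value, dtype=float) -> tuple:
    arr = np.asarray(value)
    if arr.ndim == 0:
        arr = np.full(3, arr)
    if arr.shape != (3,):
        raise ValueError(f"expected a scalar or 3-vector, got shape {arr.shape}")
    return tuple(dtype(v) for v in arr)


@dataclasses.dataclass(frozen=True)
class GridGeometry:
    """Voxel grid shape, spacing (mm/voxel) and world-space FOV center.

    The FOV center is the world coordinate of the continuous grid midpoint
    index ``(shape - 1) / 2``; it is the geometric parameter updated by the
    prospective-correction feedback loop.
    """

    shape: tuple
    spacing: tuple
    fov_center: tuple

    def __init__(self, shape, spacing, fov_center=(0.0, 0.0, 0.0)):
        object.__setattr__(self, "shape", _as_triple(shape, int))
        object.__setattr__(self, "spacing", _as_triple(spacing, float))
        object.__setattr__(self, "fov_center", _as_triple(fov_center, float))
        if any(s < 1 for s in self.shape):
            raise ValueError(f"grid shape must be >= 1 per axis, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be > 0, got {self.spacing}")
        if not all(np.isfinite(self.fov_center)):
            raise ValueError("fov_center must be finite")

    # -- derived quantities -------------------------------------------------
    @property
    def midpoint_index(self) -> np.ndarray:
        return (np.array(self.shape, dtype=float) - 1.0) / 2.0

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def fov_extent_mm(self) -> np.ndarray:
        return np.array(self.shape, dtype=float) * np.array(self.spacing)

    @property
    def is_isotropic(self) -> bool:
        return len(set(self.spacing)) == 1

    def with_center(self, fov_center) -> "GridGeometry":
        return GridGeometry(self.shape, self.spacing, _as_triple(fov_center))

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world affine (diagonal spacing convention)."""
        aff = np.eye(4)
        sp = np.array(self.spacing)
        aff[:3, :3] = np.diag(sp)
        aff[:3, 3] = np.array(self.fov_center) - sp * self.midpoint_index
        return aff


def voxel_to_world(index, geometry: GridGeometry) -> WorldPoint:
    """Map a continuous voxel index to world coordinates (mm)."""
    idx = np.asarray(index, dtype=float)
    world = (
        np.array(geometry.fov_center)
        + np.array(geometry.spacing) * (idx - geometry.midpoint_index)
    )
    return WorldPoint.from_array(world)


def world_to_voxel(point, geometry: GridGeometry) -> np.ndarray:
    """Map world coordinates (mm) to a continuous voxel index; exact inverse
    of :func:`voxel_to_world`."""
    p = np.asarray(point, dtype=float)
    return geometry.midpoint_index + (p - np.array(geometry.fov_center)) / np.array(
        geometry.spacing
    )


@dataclasses.dataclass
class VolumeGrid:
    """One repetition's image: intensities on a :class:`GridGeometry`."""

    geometry: GridGeometry
    values: np.ndarray
    repetition_index: int = 0
    te_ms: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"values shape {self.values.shape} != geometry shape "
                f"{self.geometry.shape}"
            )
        if self.repetition_index < 0:
            raise ValueError("repetition_index must be >= 0")
        if self.te_ms is not None and self.te_ms <= 0:
            raise ValueError("te_ms must be > 0")


@dataclasses.dataclass
class BinaryMask:
    """A segmentation on a :class:`GridGeometry` (True = foreground)."""

    geometry: GridGeometry
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values).astype(bool)
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"mask shape {self.values.shape} != geometry shape "
                f"{self.geometry.shape}"
            )

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def empty(self) -> bool:
        return self.voxel_count == 0

    @property
    def volume_ml(self) -> float:
        return self.voxel_count * self.geometry.voxel_volume_mm3 / 1000.0


Gridded = Union[VolumeGrid, BinaryMask]


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _geometry_from_header(img) -> GridGeometry:
    shape3 = img.shape[:3]
    zooms = img.header.get_zooms()[:3]
    affine = img.affine
    mid = (np.array(shape3, dtype=float) - 1.0) / 2.0
    center = affine[:3, :3] @ mid + affine[:3, 3]
    return GridGeometry(shape3, tuple(float(z) for z in zooms), tuple(center))


def load_volume(path) -> Union[VolumeGrid, list]:
    """Load a NIfTI image as a :class:`VolumeGrid` (3D) or a list of them (4D).

    4D files are interpreted as a dynamic series; frame ``i`` becomes the
    grid with ``repetition_index = i``.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises a zoo of types
        raise IOError(f"could not read NIfTI file {path}: {exc}") from exc
    if data.ndim not in (3, 4):
        raise ValueError(f"{path}: expected a 3D or 4D image, got {data.ndim}D")
    geom = _geometry_from_header(img)
    if data.ndim == 3:
        return VolumeGrid(geom, data.astype(np.float32))
    return [
        VolumeGrid(geom, data[..., i].astype(np.float32), repetition_index=i)
        for i in range(data.shape[-1])
    ]


def load_mask(path) -> BinaryMask:
    vol = load_volume(path)
    if isinstance(vol, list):
        raise ValueError(f"{path}: expected a 3D mask, got a 4D series")
    return BinaryMask(vol.geometry, vol.values > 0.5)


def save_volume(volume: Gridded, path) -> None:
    """Write a volume or mask as NIfTI; masks are stored as uint8 0/1."""
    path = Path(path)
    if isinstance(volume, BinaryMask):
        data = volume.values.astype(np.uint8)
    else:
        data = np.asarray(volume.values, dtype=np.float32)
    img = nib.Nifti1Image(data, volume.geometry.affine)
    img.header.set_zooms(volume.geometry.spacing)
    img.header.set_xyzt_units("mm")
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise IOError(f"could not write NIfTI file {path}: {exc}") from exc


def save_series(volumes: Sequence[VolumeGrid], path) -> None:
    """Write a repetition series as a single 4D NIfTI file."""
    if not volumes:
        raise ValueError("empty series")
    geom = volumes[0].geometry
    data = np.stack([np.asarray(v.values, dtype=np.float32) for v in volumes], axis=-1)
    img = nib.Nifti1Image(data, geom.affine)
    img.header.set_zooms(tuple(geom.spacing) + (1.0,))
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Fixed-grid preprocessing
# ---------------------------------------------------------------------------

def resample_to_isotropic(item: Gridded) -> Gridded:
    """Resample a non-isotropic grid to its smallest spacing.

    Trilinear interpolation for images, nearest-neighbour for masks; the FOV
    center is preserved.  Isotropic inputs are returned unchanged.
    """
    geom = item.geometry
    if geom.is_isotropic:
        return item
    target = float(min(geom.spacing))
    old_shape = np.array(geom.shape, dtype=float)
    old_sp = np.array(geom.spacing)
    new_shape = tuple(int(round(s * sp / target)) for s, sp in zip(geom.shape, old_sp))
    new_geom = GridGeometry(new_shape, target, geom.fov_center)
    idx = np.meshgrid(*[np.arange(n, dtype=float) for n in new_shape], indexing="ij")
    coords = [
        (idx[a] - (new_shape[a] - 1) / 2.0) * target / old_sp[a] + (old_shape[a] - 1) / 2.0
        for a in range(3)
    ]
    if isinstance(item, BinaryMask):
        out = ndimage.map_coordinates(
            item.values.astype(np.float32), coords, order=0, mode="constant", cval=0.0
        )
        return BinaryMask(new_geom, out > 0.5)
    out = ndimage.map_coordinates(
        item.values, coords, order=1, mode="constant", cval=0.0
    )
    return VolumeGrid(new_geom, out, item.repetition_index, item.te_ms)


def pad_crop_to_grid(item: Gridded, target_edge: int = 128) -> Gridded:
    """Pad and/or crop to a cubic ``target_edge**3`` grid.

    Placement is centered; padding uses 0 (air background); retained voxels
    keep their world coordinates, i.e. the output geometry's FOV center is
    shifted by any asymmetric integer offset.  Non-isotropic inputs are first
    resampled to their smallest spacing.
    """
    if target_edge < 1:
        raise ValueError("target_edge must be >= 1")
    item = resample_to_isotropic(item)
    geom = item.geometry
    src = item.values
    tgt = (int(target_edge),) * 3
    # old index `i - off` lands at new index `i`
    off = [(tgt[a] - geom.shape[a]) // 2 for a in range(3)]
    out = np.zeros(tgt, dtype=src.dtype)
    src_lo = [max(0, -off[a]) for a in range(3)]
    src_hi = [min(geom.shape[a], tgt[a] - off[a]) for a in range(3)]
    dst_lo = [src_lo[a] + off[a] for a in range(3)]
    dst_hi = [src_hi[a] + off[a] for a in range(3)]
    out[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] = src[
        src_lo[0]:src_hi[0], src_lo[1]:src_hi[1], src_lo[2]:src_hi[2]
    ]
    sp = np.array(geom.spacing)
    new_center = (
        np.array(geom.fov_center)
        + sp * ((np.array(tgt) - 1) / 2.0 - np.array(off) - geom.midpoint_index)
    )
    new_geom = GridGeometry(tgt, geom.spacing, tuple(new_center))
    if isinstance(item, BinaryMask):
        return BinaryMask(new_geom, out)
    return VolumeGrid(new_geom, out, item.repetition_index, item.te_ms)
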