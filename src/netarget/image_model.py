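"""Volume data model, coordinate conventions, NIfTI I/O and resampling.

Conventions used throughout the package:

* voxel indices are 0-based;
* world coordinates are millimetres in a RAS+ frame (negative x = left
  hemisphere, matching standard MNI reporting);
* the affine maps homogeneous voxel indices to world mm.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


class FormatError(ValueError):
    """Input file is not a NIfTI volume we can interpret."""


class DimensionalityError(ValueError):
    """Volume has an unsupported number of dimensions."""


class SpaceMismatchError(ValueError):
    """Operands live in different coordinate spaces."""


SPACE_TAGS = ("native_T1", "native_EPI", "MNI", "other")


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is singular")
    sizes = np.linalg.norm(affine[:3, :3], axis=0)
    if np.any(sizes <= 0):
        raise ValueError("voxel sizes must be strictly positive")
    return affine


@dataclass
class GridImage:
    """A 3D scalar lattice with a voxel-to-world affine (mm, RAS+)."""

    data: np.ndarray
    affine: np.ndarray
    space_tag: str = "other"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"GridImage requires 3D data, got {self.data.ndim}D"
            )
        if min(self.data.shape) < 1:
            raise ValueError("every axis must have extent >= 1")
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_sizes_mm(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def same_grid(self, other: "GridImage") -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=1e-6
        )

    def copy(self) -> "GridImage":
        return replace(self, data=self.data.copy(), affine=self.affine.copy())


@dataclass
class BinaryMask(GridImage):
    """GridImage constrained to values {0, 1}."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("BinaryMask values must be 0 or 1")
        self.data = self.data.astype(np.uint8)

    @property
    def bool_data(self) -> np.ndarray:
        return self.data.astype(bool)


@dataclass
class BoldSeries:
    """4D BOLD time series: (x, y, z, t) lattice sharing one affine."""

    data: np.ndarray
    affine: np.ndarray
    tr_seconds: float
    space_tag: str = "other"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise DimensionalityError(
                f"BoldSeries requires 4D data, got {self.data.ndim}D"
            )
        if self.data.shape[3] < 2:
            raise ValueError("BoldSeries needs at least 2 frames")
        if not self.tr_seconds > 0:
            raise ValueError("tr_seconds must be positive")
        self.affine = _check_affine(self.affine)

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]  # type: ignore[return-value]

    def frame(self, index: int) -> GridImage:
        return GridImage(self.data[..., index], self.affine, self.space_tag)

    def copy(self) -> "BoldSeries":
        return BoldSeries(
            self.data.copy(), self.affine.copy(), self.tr_seconds, self.space_tag
        )


@dataclass
class DisplacementField:
    """Dense voxelwise world-space offsets (mm), as a (x, y, z, 3) lattice.

    Applying the field to a world point p in ``source_space`` yields
    ``p + field(p)`` in ``target_space``, where field(p) is sampled
    trilinearly on the field's own grid.
    """

    data: np.ndarray
    affine: np.ndarray
    source_space: str = "other"
    target_space: str = "other"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[3] != 3:
            raise ValueError("DisplacementField must be (x, y, z, 3)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("DisplacementField values must be finite")
        self.affine = _check_affine(self.affine)

    def sample(self, world_points: np.ndarray) -> np.ndarray:
        """Trilinearly sample the 3 offset components at world points (N, 3)."""
        vox = world_to_voxel_array(self.affine, world_points)
        out = np.empty_like(world_points, dtype=float)
        for c in range(3):
            out[:, c] = ndimage.map_coordinates(
                self.data[..., c], vox.T, order=1, mode="nearest"
            )
        return out


# ---------------------------------------------------------------------------
# Coordinate mapping
# ---------------------------------------------------------------------------

def voxel_to_world(image_or_affine, voxel) -> np.ndarray:
    """Map (continuous) 0-based voxel indices to world mm."""
    affine = getattr(image_or_affine, "affine", image_or_affine)
    v = np.atleast_2d(np.asarray(voxel, dtype=float))
    if v.shape[-1] != 3:
        raise ValueError("coordinate must have 3 entries")
    w = v @ affine[:3, :3].T + affine[:3, 3]
    return w[0] if np.asarray(voxel).ndim == 1 else w


def world_to_voxel(image_or_affine, world) -> np.ndarray:
    """Map world mm to continuous 0-based voxel indices (not rounded)."""
    affine = getattr(image_or_affine, "affine", image_or_affine)
    inv = np.linalg.inv(_check_affine(affine))
    return voxel_to_world(inv, world)


def world_to_voxel_array(affine: np.ndarray, world: np.ndarray) -> np.ndarray:
    return np.atleast_2d(world_to_voxel(affine, world))


def value_at_world(image: GridImage, world, interpolation: str = "nearest"):
    """Sample an image at world coordinates (nearest or trilinear)."""
    vox = world_to_voxel_array(image.affine, np.atleast_2d(np.asarray(world, float)))
    order = {"nearest": 0, "trilinear": 1}[interpolation]
    vals = ndimage.map_coordinates(
        image.data.astype(float), vox.T, order=order, mode="constant", cval=0.0
    )
    return float(vals[0]) if np.asarray(world).ndim == 1 else vals


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_nifti(path, space_tag: str = "other"):
    """Read a 3D or 4D NIfTI-1 file into GridImage / BoldSeries."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise FormatError(f"{path} is not a readable NIfTI file: {exc}") from exc
    if not isinstance(img, (nib.Nifti1Image, nib.Nifti2Image)):
        raise FormatError(f"{path} is not a NIfTI-1 volume")
    data = np.asarray(img.dataobj)
    # squeeze trailing singleton dims (common in exported 3D files)
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim == 3:
        return GridImage(data, img.affine, space_tag)
    if data.ndim == 4:
        tr = _tr_from_header(img.header)
        return BoldSeries(data, img.affine, tr, space_tag)
    raise DimensionalityError(f"{path}: unsupported dimensionality {data.ndim}")


def _tr_from_header(header) -> float:
    zooms = header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    units = header.get_xyzt_units()[1]
    if units == "msec":
        tr /= 1e3
    elif units == "usec":
        tr /= 1e6
    return tr if tr > 0 else 1.0


def write_nifti(obj, path) -> None:
    """Write a GridImage / BinaryMask / BoldSeries / DisplacementField."""
    path = Path(path)
    if isinstance(obj, BoldSeries):
        img = nib.Nifti1Image(np.asarray(obj.data), obj.affine)
        zooms = list(img.header.get_zooms())
        zooms[3] = obj.tr_seconds
        img.header.set_zooms(zooms)
        img.header.set_xyzt_units("mm", "sec")
    elif isinstance(obj, (GridImage, DisplacementField)):
        img = nib.Nifti1Image(np.asarray(obj.data), obj.affine)
        img.header.set_xyzt_units("mm")
    else:
        raise TypeError(f"cannot write object of type {type(obj)!r}")
    nib.save(img, str(path))


def read_affine_text(path) -> np.ndarray:
    """Load a 4x4 whitespace-delimited affine from a text file."""
    mat = np.loadtxt(path)
    return _check_affine(mat)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def _target_grid(target) -> tuple[tuple[int, ...], np.ndarray, str]:
    if isinstance(target, (GridImage, BinaryMask)):
        return target.shape, target.affine, target.space_tag
    shape, affine = target[0], target[1]
    tag = target[2] if len(target) > 2 else "other"
    return tuple(shape), _check_affine(affine), tag


def resample(
    image: GridImage,
    target,
    transform=None,
    interpolation: str = "trilinear",
    fill: float = 0.0,
) -> GridImage:
    """Resample ``image`` onto a target grid.

    ``transform`` maps target world coordinates into source world
    coordinates; it is either None (identity, spaces must agree), a 4x4
    world-to-world affine, or a :class:`DisplacementField` whose
    ``source_space`` matches the target grid and ``target_space`` matches
    the source image.
    """
    if interpolation not in ("nearest", "trilinear"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    shape, t_affine, t_tag = _target_grid(target)

    if transform is None:
        if (
            image.space_tag != t_tag
            and "other" not in (image.space_tag, t_tag)
        ):
            raise SpaceMismatchError(
                f"identity transform between {t_tag!r} and {image.space_tag!r}"
            )
        if interpolation == "nearest" and image.shape == shape and np.allclose(
            image.affine, t_affine, atol=1e-9
        ):
            return GridImage(image.data.copy(), t_affine.copy(), t_tag)

    ii, jj, kk = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )
    vox = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float)
    world = np.atleast_2d(voxel_to_world(t_affine, vox))

    if transform is None:
        src_world = world
    elif isinstance(transform, DisplacementField):
        if transform.source_space != t_tag and "other" not in (
            transform.source_space,
            t_tag,
        ):
            raise SpaceMismatchError(
                f"field source {transform.source_space!r} vs target grid {t_tag!r}"
            )
        if transform.target_space != image.space_tag and "other" not in (
            transform.target_space,
            image.space_tag,
        ):
            raise SpaceMismatchError(
                f"field target {transform.target_space!r} vs image {image.space_tag!r}"
            )
        src_world = world + transform.sample(world)
    else:
        mat = np.asarray(transform, dtype=float)
        if mat.shape != (4, 4):
            raise ValueError("affine transform must be 4x4")
        src_world = world @ mat[:3, :3].T + mat[:3, 3]

    src_vox = world_to_voxel_array(image.affine, src_world)
    order = 0 if interpolation == "nearest" else 1
    vals = ndimage.map_coordinates(
        image.data.astype(float), src_vox.T, order=order, mode="constant", cval=fill
    )
    return GridImage(vals.reshape(shape), t_affine.copy(), t_tag)
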