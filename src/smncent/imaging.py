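"""NIfTI image I/O and the masked voxel-by-time representation.

Volumes are NIfTI-1 throughout: binary masks are stored as unsigned 8-bit,
statistic/centrality maps as 32-bit float, and 4D time series as 32-bit
float.  Internally everything is float64.

Voxel ordering
--------------
Whenever in-mask voxels are flattened to a vector, the order is ascending
C-order (row-major) linear index over the (x, y, z) grid, i.e. the order
returned by ``numpy.flatnonzero`` on the mask array.  This ordering is used
by every module and is stable across calls and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import DimensionalityError, FormatError, GeometryError

__all__ = [
    "ImageGrid",
    "BrainMask",
    "TimeSeriesImage",
    "VoxelMatrix",
    "read_volume",
    "read_mask",
    "read_timeseries",
    "write_volume",
    "extract_matrix",
    "insert_matrix",
    "insert_map",
]


@dataclass(frozen=True)
class ImageGrid:
    """3D voxel lattice: shape plus the affine mapping voxel -> world mm."""

    shape: tuple[int, int, int]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"grid shape must be 3 axes of >= 1 voxel, got {shape}")
        object.__setattr__(self, "shape", shape)
        if self.affine is None:
            object.__setattr__(self, "affine", np.diag([3.0, 3.0, 3.0, 1.0]))
        else:
            aff = np.asarray(self.affine, dtype=float)
            if aff.shape != (4, 4):
                raise ValueError("affine must be 4x4")
            object.__setattr__(self, "affine", aff)
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel size must be positive on all axes")

    @classmethod
    def from_voxel_size(
        cls, shape: tuple[int, int, int], voxel_size: float | tuple[float, float, float] = 3.0
    ) -> "ImageGrid":
        vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
        return cls(shape, np.diag([vs[0], vs[1], vs[2], 1.0]))

    @property
    def voxel_size(self) -> np.ndarray:
        """Edge length in mm per axis (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        """World-mm coordinates of 0-based voxel indices under this affine."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return (self.affine[:3, :3] @ ijk.T + self.affine[:3, 3:4]).T

    def matches(self, other: "ImageGrid", atol: float = 1e-4) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=atol)


@dataclass(frozen=True)
class BrainMask:
    """Binary inclusion mask on an :class:`ImageGrid`."""

    grid: ImageGrid
    indicator: np.ndarray

    def __post_init__(self) -> None:
        ind = np.asarray(self.indicator).astype(bool)
        if ind.shape != self.grid.shape:
            raise GeometryError(
                f"mask indicator shape {ind.shape} != grid shape {self.grid.shape}"
            )
        if not ind.any():
            raise ValueError("mask must contain at least one voxel")
        ind.setflags(write=False)
        object.__setattr__(self, "indicator", ind)

    @property
    def n_voxels(self) -> int:
        return int(self.indicator.sum())

    @property
    def linear_indices(self) -> np.ndarray:
        """C-order linear indices of in-mask voxels — the canonical ordering."""
        return np.flatnonzero(self.indicator)

    @property
    def voxel_coords(self) -> np.ndarray:
        """(N, 3) array of 0-based (i, j, k) coordinates in canonical order."""
        return np.stack(np.unravel_index(self.linear_indices, self.grid.shape), axis=1)


@dataclass
class TimeSeriesImage:
    """4D resting-state volume: (x, y, z, t) values plus the sampling interval."""

    grid: ImageGrid
    data: np.ndarray  # (x, y, z, T) float
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise DimensionalityError(f"expected 4D data, got {self.data.ndim}D")
        if self.data.shape[:3] != self.grid.shape:
            raise GeometryError("data spatial shape does not match grid")
        if self.data.shape[3] < 2:
            raise ValueError("time series needs at least 2 volumes")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("TR must be positive")

    @property
    def n_volumes(self) -> int:
        return int(self.data.shape[3])


@dataclass
class VoxelMatrix:
    """In-mask voxel x time matrix; row i is the i-th canonical mask voxel."""

    mask: BrainMask
    data: np.ndarray  # (N, T)
    standardized: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DimensionalityError("voxel matrix must be 2D (voxels x time)")
        if self.data.shape[0] != self.mask.n_voxels:
            raise GeometryError(
                f"row count {self.data.shape[0]} != mask voxel count {self.mask.n_voxels}"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_timepoints(self) -> int:
        return int(self.data.shape[1])


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _load(path) -> nib.Nifti1Image:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise FormatError(f"cannot read {path!r} as a NIfTI image: {exc}") from exc
    return img


def read_timeseries(path, tr_seconds: float | None = None) -> TimeSeriesImage:
    """Read a 4D NIfTI as a :class:`TimeSeriesImage`.

    TR is taken from the header's 4th zoom unless given explicitly.
    """
    img = _load(path)
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 4:
        raise DimensionalityError(f"{path}: expected 4D image, got {data.ndim}D")
    if tr_seconds is None:
        zooms = img.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
    grid = ImageGrid(data.shape[:3], np.asarray(img.affine))
    return TimeSeriesImage(grid, data, tr_seconds)


def read_mask(path) -> BrainMask:
    """Read a 3D NIfTI as a binary mask (any nonzero voxel is in-mask)."""
    img = _load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise DimensionalityError(f"{path}: expected 3D mask image, got {data.ndim}D")
    grid = ImageGrid(data.shape, np.asarray(img.affine))
    return BrainMask(grid, data != 0)


def read_volume(path) -> "TimeSeriesImage | BrainMask | tuple[ImageGrid, np.ndarray]":
    """Dispatch on dimensionality: 4D -> TimeSeriesImage, 3D -> (grid, values).

    3D files are returned as raw (grid, float array) pairs because a 3D
    volume may be a mask, a tissue-probability map or a statistic map; use
    :func:`read_mask` when a mask is required.
    """
    img = _load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4:
        return read_timeseries(path)
    if data.ndim == 3:
        grid = ImageGrid(data.shape, np.asarray(img.affine))
        return grid, data.astype(float)
    raise DimensionalityError(f"{path}: unsupported dimensionality {data.ndim}")


def write_volume(obj, path, grid: ImageGrid | None = None) -> Path:
    """Write a mask, time series or 3D map to NIfTI-1.

    Masks go out as uint8, everything else as float32.  Raw ndarrays need an
    explicit ``grid``.
    """
    path = Path(path)
    if isinstance(obj, BrainMask):
        img = nib.Nifti1Image(obj.indicator.astype(np.uint8), obj.grid.affine)
    elif isinstance(obj, TimeSeriesImage):
        img = nib.Nifti1Image(obj.data.astype(np.float32), obj.grid.affine)
        zooms = tuple(obj.grid.voxel_size) + (obj.tr_seconds,)
        img.header.set_zooms(zooms)
    else:
        if grid is None:
            raise ValueError("writing a raw array requires an explicit grid")
        arr = np.asarray(obj, dtype=np.float32)
        img = nib.Nifti1Image(arr, grid.affine)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# Grid <-> matrix conversion
# ---------------------------------------------------------------------------

def extract_matrix(img: TimeSeriesImage, mask: BrainMask) -> VoxelMatrix:
    """Pull in-mask time courses into an (N, T) matrix in canonical order."""
    if not img.grid.matches(mask.grid):
        raise GeometryError("time series grid does not match mask grid")
    data = img.data.reshape(-1, img.n_volumes)[mask.linear_indices]
    return VoxelMatrix(mask, data.copy(), standardized=False)


def insert_matrix(
    vm: VoxelMatrix, tr_seconds: float = 2.0, fill: float = 0.0
) -> TimeSeriesImage:
    """Inverse of :func:`extract_matrix`; out-of-mask voxels get ``fill``."""
    grid = vm.mask.grid
    out = np.full((grid.n_voxels, vm.n_timepoints), fill, dtype=float)
    out[vm.mask.linear_indices] = vm.data
    return TimeSeriesImage(grid, out.reshape(grid.shape + (vm.n_timepoints,)), tr_seconds)


def insert_map(values: np.ndarray, mask: BrainMask, fill: float = 0.0) -> np.ndarray:
    """Scatter per-voxel values back onto the 3D grid (canonical order)."""
    values = np.asarray(values, dtype=float)
    if values.shape != (mask.n_voxels,):
        raise GeometryError(
            f"expected {mask.n_voxels} values, got shape {values.shape}"
        )
    flat = np.full(mask.grid.n_voxels, fill, dtype=float)
    flat[mask.linear_indices] = values
    return flat.reshape(mask.grid.shape)
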