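"""Volume container, NIfTI-1 I/O, resampling and multiresolution pyramids.

All spatial reasoning in this package happens in world coordinates (mm): a
:class:`Volume` couples a 3-D scalar array with the 4x4 voxel-index-to-world
affine from its NIfTI header.  Resampling follows the pull-back convention
(iterate over the fixed grid, sample the moving image at transformed
coordinates), which is the standard arrangement in neuroimaging registration
and makes transform composition associative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume",
    "Pyramid",
    "VolumeError",
    "FourDimensionalInputError",
    "NaNVoxelError",
    "NonInvertibleAffineError",
    "PyramidError",
    "load_volume",
    "save_volume",
    "resample",
    "sample_at_world",
    "build_pyramid",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class VolumeError(Exception):
    """Base class for volume handling errors."""


class FourDimensionalInputError(VolumeError):
    """Raised when a file holds more than a single 3-D frame."""


class NaNVoxelError(VolumeError):
    """Raised when a loaded image contains NaN voxels."""


class NonInvertibleAffineError(VolumeError):
    """Raised when a voxel-to-world affine is singular."""


@dataclass
class Volume:
    """A 3-D scalar grid with a voxel-index -> world-mm affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeError(f"expected 3-D data, got ndim={self.data.ndim}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise VolumeError(f"affine must be 4x4, got {self.affine.shape}")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise NonInvertibleAffineError("voxel-to-world affine is singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Voxel edge lengths in mm along each axis."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.affine.copy())

    def like(self, data: np.ndarray) -> "Volume":
        """A new volume with the same grid but different data."""
        return Volume(np.asarray(data), self.affine.copy())

    def same_grid(self, other: "Volume", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices to world mm coordinates."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def grid_world_coordinates(self, stride: int = 1) -> np.ndarray:
        """World coordinates of all voxel centres, C-ordered, shape (N, 3)."""
        idx = np.indices(self.shape, dtype=float)[:, ::stride, ::stride, ::stride]
        flat = idx.reshape(3, -1).T
        return self.voxel_to_world(flat)

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned world bounding box of the eight grid corners."""
        n = np.asarray(self.shape, dtype=float) - 1.0
        corners = np.array(
            [[i, j, k] for i in (0, n[0]) for j in (0, n[1]) for k in (0, n[2])]
        )
        w = self.voxel_to_world(corners)
        return w.min(axis=0), w.max(axis=0)


@dataclass
class Pyramid:
    """Multiresolution stack of a volume, coarsest level first."""

    levels: list[Volume]
    factors: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.levels)

    def __getitem__(self, i: int) -> Volume:
        return self.levels[i]


class PyramidError(VolumeError):
    """Raised when a volume is too small for the requested pyramid."""


def load_volume(path: str | Path) -> Volume:
    """Load a single-frame NIfTI-1 volume as float data.

    The affine is nibabel's best affine (sform preferred over qform when
    present, per NIfTI convention).  Raises :class:`FileNotFoundError`,
    :class:`FourDimensionalInputError` or :class:`NaNVoxelError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    # tolerate trailing singleton dims, reject genuine multi-frame input
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FourDimensionalInputError(
            f"{path} has shape {img.shape}; only single-frame 3-D volumes are supported"
        )
    data = np.asarray(data, dtype=np.float64)
    if np.isnan(data).any():
        raise NaNVoxelError(f"{path} contains NaN voxels")
    return Volume(data, np.asarray(img.affine, dtype=float))


def save_volume(vol: Volume, path: str | Path) -> None:
    """Write a volume as float32 NIfTI-1 (.nii or .nii.gz)."""
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine)
    img.header.set_data_dtype(np.float32)
    nib.save(img, str(path))


_ORDER = {"trilinear": 1, "nearest": 0}


def sample_at_world(vol: Volume, pts: np.ndarray, interpolation: str = "trilinear") -> np.ndarray:
    """Sample ``vol`` at world-mm points ``pts`` (N, 3); outside -> 0."""
    order = _ORDER[interpolation]
    idx = vol.world_to_voxel(pts)
    return ndimage.map_coordinates(
        vol.data, idx.T, order=order, mode="grid-constant", cval=0.0, prefilter=False
    )


def resample(
    moving: Volume,
    transform,
    target_grid: Volume,
    interpolation: str = "trilinear",
) -> Volume:
    """Pull-back resampling of ``moving`` onto ``target_grid``.

    ``transform`` maps target-grid world coordinates into moving-volume world
    coordinates; ``None`` means identity.  Voxels mapping outside the moving
    volume are filled with 0.  Use ``interpolation='nearest'`` for label
    volumes.
    """
    if interpolation not in _ORDER:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    pts = target_grid.grid_world_coordinates()
    if transform is not None:
        pts = transform.map_points(pts)
    vals = sample_at_world(moving, pts, interpolation)
    out = vals.reshape(target_grid.shape)
    if interpolation == "nearest":
        out = out.astype(moving.data.dtype, copy=False)
    return Volume(out, target_grid.affine.copy())


def build_pyramid(
    v: Volume,
    n_levels: int = 3,
    smoothing_fwhm_voxels: float = 2.0,
) -> Pyramid:
    """Gaussian-smooth-and-subsample pyramid; finest level is the input.

    Each reduction halves the grid after pre-smoothing with the given FWHM
    (in voxels of the level being reduced).  Every level must keep at least
    8 voxels per axis.
    """
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    levels = [v]
    sigma = smoothing_fwhm_voxels * FWHM_TO_SIGMA
    cur = v
    for _ in range(n_levels - 1):
        if min(cur.shape) // 2 < 8:
            raise PyramidError(
                f"volume of shape {cur.shape} too small for {n_levels} pyramid levels"
            )
        sm = ndimage.gaussian_filter(np.asarray(cur.data, dtype=float), sigma)
        sub = sm[::2, ::2, ::2]
        aff = cur.affine.copy()
        aff[:3, :3] *= 2.0
        cur = Volume(sub, aff)
        levels.append(cur)
    levels = levels[::-1]
    factors = [2 ** (len(levels) - 1 - k) for k in range(len(levels))]
    return Pyramid(levels=levels, factors=factors)
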