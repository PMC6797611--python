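"""In-memory containers for volumetric brain data, with NIfTI-1 I/O.

Volumes are treated as abstract 3D (or 4D) grids: the affine is carried
through I/O untouched and no resampling is ever performed internally.
Inputs that need to share a grid (a subject's map and its warped atlas)
must already be on that grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np


class BrainglanceError(Exception):
    """Base class for errors raised by this package."""


class ValidationError(BrainglanceError):
    """An input violates a documented contract."""


def _check_voxel_size(voxel_size) -> tuple[float, float, float]:
    vs = tuple(float(v) for v in voxel_size)
    if len(vs) != 3 or any(v <= 0 for v in vs):
        raise ValidationError(f"voxel_size must be 3 positive values, got {voxel_size!r}")
    return vs


@dataclass
class LabelVolume:
    """3D integer parcellation grid; 0 is background.

    Label volumes must only ever be produced or resampled with
    nearest-neighbor interpolation so that labels stay integral.
    """

    grid: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    space_tag: str = ""
    affine: np.ndarray | None = None

    def __post_init__(self):
        grid = np.asarray(self.grid)
        if grid.ndim != 3:
            raise ValidationError(f"label volume must be 3D, got shape {grid.shape}")
        if np.issubdtype(grid.dtype, np.floating):
            if not np.all(np.isfinite(grid)) or not np.all(grid == np.round(grid)):
                raise ValidationError(
                    "label volume contains non-integer values; labels must be "
                    "integers (resample with nearest-neighbor interpolation)"
                )
            grid = grid.astype(np.int64)
        elif not np.issubdtype(grid.dtype, np.integer):
            raise ValidationError(f"label volume has non-numeric dtype {grid.dtype}")
        if grid.min() < 0:
            raise ValidationError("label volume contains negative labels")
        self.grid = grid
        self.voxel_size = _check_voxel_size(self.voxel_size)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.grid.shape

    def labels(self) -> np.ndarray:
        """Sorted nonzero labels present in the grid."""
        u = np.unique(self.grid)
        return u[u > 0]


@dataclass
class ScalarVolume:
    """3D scalar map (GLM contrast, centrality, homogeneity, ...)."""

    grid: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    space_tag: str = ""
    affine: np.ndarray | None = None

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=np.float64)
        if grid.ndim != 3:
            raise ValidationError(f"scalar volume must be 3D, got shape {grid.shape}")
        self.grid = grid
        self.voxel_size = _check_voxel_size(self.voxel_size)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.grid.shape


@dataclass
class TimeSeriesVolume:
    """4D (x, y, z, t) BOLD-like time series with an in-brain mask.

    Masked-in voxels must have finite series; at least two time points
    are required.
    """

    grid: np.ndarray
    tr_seconds: float
    mask: np.ndarray | None = None
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    space_tag: str = ""
    affine: np.ndarray | None = None

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=np.float64)
        if grid.ndim != 4:
            raise ValidationError(f"time series volume must be 4D, got shape {grid.shape}")
        if grid.shape[3] < 2:
            raise ValidationError("time series needs at least 2 volumes")
        if self.tr_seconds <= 0:
            raise ValidationError("tr_seconds must be positive")
        if self.mask is None:
            mask = np.ones(grid.shape[:3], dtype=bool)
        else:
            mask = np.asarray(self.mask).astype(bool)
            if mask.shape != grid.shape[:3]:
                raise ValidationError(
                    f"mask shape {mask.shape} does not match spatial shape {grid.shape[:3]}"
                )
        if not np.all(np.isfinite(grid[mask])):
            raise ValidationError("masked-in voxels contain non-finite samples")
        self.grid = grid
        self.mask = mask
        self.voxel_size = _check_voxel_size(self.voxel_size)

    @property
    def n_timepoints(self) -> int:
        return self.grid.shape[3]

    def masked_data(self) -> np.ndarray:
        """(n_voxels, T) matrix of the masked-in series, C-order of the mask."""
        return self.grid[self.mask]


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine_or_default(vol) -> np.ndarray:
    if vol.affine is not None:
        return np.asarray(vol.affine, dtype=float)
    aff = np.diag(list(vol.voxel_size) + [1.0])
    return aff


def load_label_volume(path, space_tag: str | None = None) -> LabelVolume:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    return LabelVolume(
        grid=np.asanyarray(img.dataobj),
        voxel_size=zooms,
        space_tag=space_tag if space_tag is not None else Path(str(path)).stem,
        affine=np.asarray(img.affine),
    )


def load_scalar_volume(path, space_tag: str | None = None) -> ScalarVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return ScalarVolume(
        grid=data,
        voxel_size=img.header.get_zooms()[:3],
        space_tag=space_tag if space_tag is not None else Path(str(path)).stem,
        affine=np.asarray(img.affine),
    )


def load_timeseries(path, tr_seconds: float | None = None, mask: np.ndarray | None = None) -> TimeSeriesVolume:
    """Load a 4D NIfTI; TR read from the header's 4th zoom unless given."""
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    if tr_seconds is None:
        if len(zooms) < 4 or zooms[3] <= 0:
            raise ValidationError(f"no usable TR in header of {path}; pass tr_seconds")
        tr_seconds = float(zooms[3])
    return TimeSeriesVolume(
        grid=np.asanyarray(img.dataobj, dtype=np.float64),
        tr_seconds=tr_seconds,
        mask=mask,
        voxel_size=zooms[:3],
        space_tag=Path(str(path)).stem,
        affine=np.asarray(img.affine),
    )


def save_volume(vol, path) -> None:
    """Write a LabelVolume / ScalarVolume / TimeSeriesVolume as NIfTI-1."""
    grid = vol.grid
    if isinstance(vol, LabelVolume):
        grid = grid.astype(np.int32)
    img = nib.Nifti1Image(grid, _affine_or_default(vol))
    zooms = list(vol.voxel_size)
    if grid.ndim == 4:
        zooms.append(getattr(vol, "tr_seconds", 1.0))
    img.header.set_zooms(zooms)
    nib.save(img, str(path))
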