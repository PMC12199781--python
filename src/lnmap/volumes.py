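"""Volume grid, mask and NIfTI I/O shared by every pipeline stage.

All stages operate on a single shared :class:`VolumeGrid`: inputs must
already live on the same voxel grid (registration / resampling is out of
scope — a mismatch is an error, never a silent resample).  Voxel-wise
statistics are computed only over the brain-mask voxels, enumerated in a
fixed row-major order by :func:`in_mask_indices`; written statistic maps
put 0 at out-of-mask voxels for viewer compatibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeGrid",
    "Volume",
    "LesionMask",
    "GridMismatchError",
    "read_volume",
    "write_volume",
    "in_mask_indices",
]

VolumeKind = Literal["binary", "count", "statistic", "label"]


class GridMismatchError(ValueError):
    """Raised when a volume does not share the pipeline's voxel grid."""


@dataclass(frozen=True)
class VolumeGrid:
    """A voxel grid: dimensions, world mapping and brain mask.

    Parameters
    ----------
    shape
        Voxels per axis (all >= 1).
    affine
        4x4 voxel->world (mm) map; must be invertible.
    brain_mask
        Boolean array of ``shape`` with at least one True voxel.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray
    brain_mask: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"grid shape must be three positive ints, got {shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "affine", affine)
        mask = np.asarray(self.brain_mask).astype(bool)
        if mask.shape != shape:
            raise ValueError("brain_mask shape does not match grid shape")
        if not mask.any():
            raise ValueError("brain_mask has no foreground voxel")
        object.__setattr__(self, "brain_mask", mask)

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        """Voxel edge lengths in mm (column norms of the linear part)."""
        return tuple(float(n) for n in np.linalg.norm(self.affine[:3, :3], axis=0))

    @property
    def n_in_mask(self) -> int:
        return int(self.brain_mask.sum())

    def world_coords(self, ijk: np.ndarray) -> np.ndarray:
        """Map (n, 3) voxel indices to (n, 3) world mm coordinates."""
        ijk = np.atleast_2d(ijk)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def matches(self, other: "VolumeGrid", atol: float = 1e-4) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


def in_mask_indices(grid: VolumeGrid) -> np.ndarray:
    """Flat (row-major, C-order) indices of all brain-mask voxels.

    Every voxel-wise vector in the pipeline follows this ordering; the
    same grid always yields the same ordering.
    """
    idx = np.flatnonzero(grid.brain_mask.ravel(order="C"))
    if idx.size == 0:
        raise ValueError("brain mask is empty")
    return idx


@dataclass
class Volume:
    """A value per voxel on a shared grid.

    ``kind`` declares the content contract: binary volumes hold only
    {0, 1}, count volumes non-negative integers, label volumes
    non-negative integer codes, statistic volumes any finite reals.
    """

    grid: VolumeGrid
    data: np.ndarray
    kind: VolumeKind = "statistic"

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.shape != self.grid.shape:
            raise ValueError(
                f"data shape {data.shape} does not match grid {self.grid.shape}"
            )
        if self.kind == "binary":
            vals = np.unique(data)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError(
                    f"binary volume contains values other than 0/1: {vals[:5]}"
                )
            data = data.astype(np.uint8)
        elif self.kind in ("count", "label"):
            if (data < 0).any() or not np.equal(np.mod(data, 1), 0).all():
                raise ValueError(f"{self.kind} volume must hold non-negative integers")
            data = data.astype(np.int32)
        else:
            data = data.astype(np.float64, copy=False)
        self.data = data

    # -- mask-vector plumbing -------------------------------------------------

    def in_mask_vector(self) -> np.ndarray:
        """Values at brain-mask voxels, in `in_mask_indices` order."""
        return self.data.ravel(order="C")[in_mask_indices(self.grid)]

    @classmethod
    def from_vector(
        cls, grid: VolumeGrid, vec: np.ndarray, kind: VolumeKind = "statistic"
    ) -> "Volume":
        """Scatter an in-mask vector back to a full volume (0 outside)."""
        vec = np.asarray(vec)
        idx = in_mask_indices(grid)
        if vec.shape != (idx.size,):
            raise ValueError(f"vector length {vec.shape} != {idx.size} in-mask voxels")
        flat = np.zeros(int(np.prod(grid.shape)), dtype=vec.dtype)
        flat[idx] = vec
        return cls(grid, flat.reshape(grid.shape), kind=kind)

    def foreground_indices(self) -> np.ndarray:
        """Flat indices (C-order) of nonzero voxels."""
        return np.flatnonzero(self.data.ravel(order="C"))


@dataclass
class LesionMask:
    """One literature case's lesion tracing: a binary seed volume.

    Non-contiguous foci are allowed and treated as a single seed, since
    all lesions belonging to one reported case form one mask.
    """

    case_id: str
    volume: Volume

    def __post_init__(self) -> None:
        if self.volume.kind != "binary":
            raise ValueError("lesion mask must be a binary volume")
        fg = self.volume.data.astype(bool)
        if not fg.any():
            raise ValueError(f"lesion {self.case_id!r} has no foreground voxel")
        if (fg & ~self.volume.grid.brain_mask).any():
            raise ValueError(f"lesion {self.case_id!r} extends outside the brain mask")

    @property
    def n_voxels(self) -> int:
        return int(self.volume.data.sum())


_NIFTI_DTYPES = {"binary": np.uint8, "count": np.int32, "label": np.int16,
                 "statistic": np.float32}


def write_volume(volume: Volume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 (.nii / .nii.gz; gzip by extension)."""
    path = Path(path)
    dtype = _NIFTI_DTYPES[volume.kind]
    img = nib.Nifti1Image(volume.data.astype(dtype), volume.grid.affine)
    img.to_filename(str(path))
    return path


def read_volume(
    path: str | Path,
    grid: VolumeGrid | None = None,
    kind: VolumeKind = "statistic",
) -> Volume:
    """Read a 3-D NIfTI-1 volume, optionally validating it against a grid.

    Raises
    ------
    GridMismatchError
        If ``grid`` is given and shape or affine differ beyond tolerance.
    ValueError
        If the file is not 3-D, or the data violate the declared ``kind``
        (e.g. non-{0,1} values declared binary).
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got {data.ndim}-D")
    if grid is not None:
        if tuple(data.shape) != grid.shape:
            raise GridMismatchError(
                f"{path}: shape {data.shape} != grid {grid.shape}"
            )
        if not np.allclose(img.affine, grid.affine, atol=1e-4):
            raise GridMismatchError(f"{path}: affine differs from grid affine")
        out_grid = grid
    else:
        mask = np.ones(data.shape, dtype=bool)
        out_grid = VolumeGrid(tuple(data.shape), np.asarray(img.affine), mask)
    return Volume(out_grid, data, kind=kind)


def read_lesion_masks(
    paths: Iterable[str | Path], grid: VolumeGrid
) -> list[LesionMask]:
    """Read a cohort of binary lesion masks; case_id = file stem."""
    masks = []
    for p in paths:
        p = Path(p)
        vol = read_volume(p, grid=grid, kind="binary")
        case_id = p.name.removesuffix(".gz").removesuffix(".nii")
        masks.append(LesionMask(case_id, vol))
    return masks
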