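"""4D volume container and NIfTI-1 I/O.

All spatial statistics in the pipeline operate on the flattened in-mask
voxel vector; voxel order is the file's native array order (C order of the
``(X, Y, Z)`` grid restricted to the mask).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "Volume4D",
    "read_volume4d",
    "write_volume4d",
    "read_mask",
    "write_mask",
    "read_maps4d",
    "write_maps4d",
]


@dataclass
class Volume4D:
    """One subject's masked 4D scan.

    Parameters
    ----------
    data
        ``(X, Y, Z, T)`` real array.
    tr_seconds
        Repetition time (sampling interval) in seconds; must be positive.
    mask
        ``(X, Y, Z)`` boolean array of brain voxels. Statistics are
        computed over in-mask voxels only.
    """

    data: np.ndarray
    tr_seconds: float
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("not a 4D time series")
        if self.data.shape[3] < 2:
            raise ValueError("need at least 2 time points")
        if not self.tr_seconds > 0:
            raise ValueError(f"non-positive TR: {self.tr_seconds}")
        if self.mask is None:
            self.mask = self.data.var(axis=3) > 0
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match spatial shape "
                f"{self.data.shape[:3]}"
            )

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def n_voxels(self) -> int:
        """Number of in-mask voxels."""
        return int(self.mask.sum())

    def in_mask_matrix(self) -> np.ndarray:
        """Return the ``(T, V)`` matrix of in-mask voxel time series."""
        return self.data[self.mask].T.copy()

    def with_in_mask_matrix(self, matrix: np.ndarray) -> "Volume4D":
        """Build a new volume from a ``(T, V)`` in-mask matrix.

        Out-of-mask voxels are set to zero.
        """
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (self.n_timepoints, self.n_voxels):
            raise ValueError(
                f"expected matrix of shape {(self.n_timepoints, self.n_voxels)}, "
                f"got {matrix.shape}"
            )
        data = np.zeros_like(self.data)
        data[self.mask] = matrix.T
        return Volume4D(data=data, tr_seconds=self.tr_seconds, mask=self.mask.copy())


def read_volume4d(
    path: str | os.PathLike,
    mask_path: str | os.PathLike | None = None,
    tr_seconds: float | None = None,
) -> Volume4D:
    """Read a 4D NIfTI file into a :class:`Volume4D`.

    TR is taken from the file's time-step metadata unless ``tr_seconds``
    overrides it. When no mask file is given, the mask defaults to voxels
    with nonzero temporal variance.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: not a 4D time series (got {data.ndim} dims)")
    if tr_seconds is None:
        zooms = img.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 else 0.0
    if not tr_seconds > 0:
        raise ValueError(f"{path}: non-positive TR ({tr_seconds})")
    mask = read_mask(mask_path) if mask_path is not None else None
    return Volume4D(data=data, tr_seconds=float(tr_seconds), mask=mask)


def write_volume4d(vol: Volume4D, path: str | os.PathLike) -> None:
    """Write a :class:`Volume4D` as NIfTI-1, storing TR in the time zoom."""
    img = nib.Nifti1Image(vol.data.astype(np.float64), affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, vol.tr_seconds))
    img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, str(path))


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a 3D NIfTI mask as a boolean array (nonzero voxels)."""
    if not os.path.exists(path):
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: mask must be 3D (got {data.ndim} dims)")
    return data != 0


def write_mask(mask: np.ndarray, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine=np.eye(4))
    nib.save(img, str(path))


def read_maps4d(path: str | os.PathLike) -> np.ndarray:
    """Read a stack of K 3D maps stored as one 4D NIfTI, as ``(X,Y,Z,K)``."""
    if not os.path.exists(path):
        raise FileNotFoundError(str(path))
    data = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D map stack")
    return data


def write_maps4d(maps: np.ndarray, path: str | os.PathLike) -> None:
    """Write a ``(X,Y,Z,K)`` stack of 3D maps as one 4D NIfTI."""
    img = nib.Nifti1Image(np.asarray(maps, dtype=np.float64), affine=np.eye(4))
    nib.save(img, str(path))
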