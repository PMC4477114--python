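"""Dual regression: subject time courses then subject spatial maps.

Stage 1 regresses the group spatial maps (as spatial regressors in one
multiple regression, plus intercept) into the subject's 4D data, giving a
subject-specific time course per group map. Stage 2 regresses those time
courses (as temporal regressors, again jointly) back into the same data,
giving subject-specific spatial maps, which are then z-scored.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ica import GroupICs, zscore_map
from .volume import Volume4D, write_maps4d

__all__ = [
    "SubjectNetworkTimecourses",
    "SubjectSpatialMaps",
    "spatial_regression",
    "temporal_regression",
    "dual_regress",
]

_MAX_CONDITION = 1e8


@dataclass
class SubjectNetworkTimecourses:
    """T x K subject-specific network time courses (stage-1 output)."""

    values: np.ndarray
    component_ids: list[str]
    subject_id: str
    variance_normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time courses must be T x K")
        if self.values.shape[1] != len(self.component_ids):
            raise ValueError("component_ids length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite time course values")
        if self.variance_normalized:
            sd = self.values.std(axis=0)
            if not np.allclose(sd[sd > 0], 1.0, atol=1e-6):
                raise ValueError("variance_normalized set but columns not unit-SD")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.component_ids)

    def save(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def load(
        cls, path: str | os.PathLike, subject_id: str, variance_normalized: bool = False
    ) -> "SubjectNetworkTimecourses":
        df = pd.read_csv(path, sep="\t")
        return cls(
            values=df.to_numpy(dtype=float),
            component_ids=list(df.columns),
            subject_id=subject_id,
            variance_normalized=variance_normalized,
        )


@dataclass
class SubjectSpatialMaps:
    """(X, Y, Z, K) z-scored subject-specific maps (stage-2 output)."""

    maps: np.ndarray
    mask: np.ndarray
    subject_id: str

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.maps.ndim != 4 or self.maps.shape[:3] != self.mask.shape:
            raise ValueError("maps must be (X, Y, Z, K) on the mask grid")

    @property
    def n_components(self) -> int:
        return self.maps.shape[3]

    def in_mask_maps(self) -> np.ndarray:
        return self.maps[self.mask].T.copy()

    def save(self, path: str | os.PathLike) -> None:
        write_maps4d(self.maps, path)


def _check_condition(design: np.ndarray, what: str) -> None:
    centered = design - design.mean(axis=0, keepdims=True)
    cond = np.linalg.cond(centered)
    if cond > _MAX_CONDITION:
        raise ValueError(f"collinear {what} (condition number {cond:.3g})")


def spatial_regression(
    vol: Volume4D,
    group_maps: GroupICs,
    variance_normalize: bool = True,
    subject_id: str = "",
) -> SubjectNetworkTimecourses:
    """Stage 1: joint regression of group maps into the subject's data.

    For each time point, the in-mask voxel vector is regressed on the K
    group maps plus an intercept; coefficient k at time t is network k's
    time course value at t. Columns are variance-normalized (unit SD)
    when ``variance_normalize`` is set.
    """
    if vol.spatial_shape != group_maps.mask.shape or not np.array_equal(
        vol.mask, group_maps.mask
    ):
        raise ValueError("volume and group maps must share grid and mask")
    M = group_maps.in_mask_maps().T  # V x K
    V, K = M.shape
    if K > V:
        raise ValueError("more maps than in-mask voxels")
    _check_condition(M, "group maps")
    design = np.column_stack([np.ones(V), M])
    Y = vol.in_mask_matrix().T  # V x T
    coef, *_ = np.linalg.lstsq(design, Y, rcond=None)
    tcs = coef[1:].T  # T x K
    if variance_normalize:
        sd = tcs.std(axis=0)
        nz = sd > 0
        tcs[:, nz] /= sd[nz]
    return SubjectNetworkTimecourses(
        values=tcs,
        component_ids=[f"IC{k}" for k in range(K)],
        subject_id=subject_id,
        variance_normalized=variance_normalize,
    )


def temporal_regression(
    vol: Volume4D, tcs: SubjectNetworkTimecourses
) -> SubjectSpatialMaps:
    """Stage 2: joint regression of the time courses into the same data.

    Each in-mask voxel's series is regressed on the K time courses plus an
    intercept; coefficient map k is z-scored over the mask.
    """
    T, K = tcs.values.shape
    if T != vol.n_timepoints:
        raise ValueError("time course length does not match volume")
    _check_condition(tcs.values, "time courses")
    design = np.column_stack([np.ones(T), tcs.values])
    Y = vol.in_mask_matrix()  # T x V
    coef, *_ = np.linalg.lstsq(design, Y, rcond=None)
    maps = np.zeros(vol.spatial_shape + (K,))
    for k in range(K):
        flat = np.zeros(vol.spatial_shape)
        flat[vol.mask] = coef[k + 1]
        maps[..., k] = zscore_map(flat, vol.mask)
    return SubjectSpatialMaps(maps=maps, mask=vol.mask, subject_id=tcs.subject_id)


def dual_regress(
    vol: Volume4D,
    group_maps: GroupICs,
    variance_normalize: bool = True,
    subject_id: str = "",
) -> tuple[SubjectNetworkTimecourses, SubjectSpatialMaps]:
    """Run both dual-regression stages for one subject (deterministic)."""
    tcs = spatial_regression(
        vol, group_maps, variance_normalize=variance_normalize, subject_id=subject_id
    )
    maps = temporal_regression(vol, tcs)
    return tcs, maps
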