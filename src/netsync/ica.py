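"""Temporally concatenated group spatial ICA.

Subjects are stacked along time after voxelwise variance normalization,
reduced by PCA to the requested number of components, and unmixed with
FastICA so that the *spatial maps* are the independent sources and the
temporal mixing matrix carries the time courses. Each map is z-scored
over the brain mask and sign-oriented so its skewness is non-negative.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning
from sklearn.utils.extmath import randomized_svd

from .config import child_seed
from .volume import Volume4D, read_maps4d, write_maps4d

__all__ = [
    "GroupICs",
    "concatenate_subjects",
    "fit_spatial_ica",
    "zscore_map",
]


@dataclass
class GroupICs:
    """Group-level spatial components.

    ``maps`` is a ``(X, Y, Z, K)`` stack of z-scored spatial maps (in-mask
    mean 0, population SD 1); ``mixing`` is the ``(sum-of-T, K)`` temporal
    mixing matrix fitted against the concatenated data;
    ``explained_variance`` holds the PCA reduction's variance ratios.
    """

    maps: np.ndarray
    mixing: np.ndarray
    mask: np.ndarray
    explained_variance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.maps.ndim != 4:
            raise ValueError("maps must be a (X, Y, Z, K) stack")
        if self.maps.shape[:3] != self.mask.shape:
            raise ValueError("maps grid does not match mask")
        if self.explained_variance is None:
            self.explained_variance = np.full(self.n_components, np.nan)

    @property
    def n_components(self) -> int:
        return self.maps.shape[3]

    def in_mask_maps(self) -> np.ndarray:
        """Return the ``(K, V)`` matrix of in-mask map values."""
        return self.maps[self.mask].T.copy()

    def save(self, out_dir: str | os.PathLike) -> None:
        os.makedirs(out_dir, exist_ok=True)
        write_maps4d(self.maps, os.path.join(out_dir, "group_maps.nii"))
        from .volume import write_mask

        write_mask(self.mask, os.path.join(out_dir, "mask.nii"))
        pd.DataFrame(
            self.mixing, columns=[f"IC{k}" for k in range(self.n_components)]
        ).to_csv(os.path.join(out_dir, "mixing.tsv"), sep="\t", index=False)
        pd.DataFrame(
            {"component": np.arange(self.n_components),
             "explained_variance_ratio": self.explained_variance}
        ).to_csv(os.path.join(out_dir, "explained_variance.tsv"), sep="\t", index=False)

    @classmethod
    def load(cls, out_dir: str | os.PathLike) -> "GroupICs":
        from .volume import read_mask

        maps = read_maps4d(os.path.join(out_dir, "group_maps.nii"))
        mask = read_mask(os.path.join(out_dir, "mask.nii"))
        mixing = pd.read_csv(
            os.path.join(out_dir, "mixing.tsv"), sep="\t"
        ).to_numpy(dtype=float)
        ev = pd.read_csv(
            os.path.join(out_dir, "explained_variance.tsv"), sep="\t"
        )["explained_variance_ratio"].to_numpy(dtype=float)
        return cls(maps=maps, mixing=mixing, mask=mask, explained_variance=ev)


def concatenate_subjects(volumes: list[Volume4D]) -> np.ndarray:
    """Stack subjects' in-mask matrices along time, in subject order.

    Each subject's block is voxelwise demeaned and variance-normalized
    before stacking so high-variance subjects cannot dominate the group
    decomposition. Zero-variance voxels map to zero columns in that block.
    """
    if not volumes:
        raise ValueError("no volumes to concatenate")
    ref = volumes[0]
    blocks = []
    for i, vol in enumerate(volumes):
        if vol.spatial_shape != ref.spatial_shape or not np.array_equal(
            vol.mask, ref.mask
        ):
            raise ValueError(f"subject {i}: grid or mask mismatch")
        block = vol.in_mask_matrix()
        block = block - block.mean(axis=0, keepdims=True)
        sd = block.std(axis=0)
        nz = sd > 0
        block[:, nz] /= sd[nz]
        blocks.append(block)
    return np.vstack(blocks)


def zscore_map(map3d: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Z-score a spatial map over the mask (population SD); zeros outside.

    Normalizes each voxel's intensity with respect to the intensity of all
    in-mask voxels of the map.
    """
    map3d = np.asarray(map3d, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if map3d.shape != mask.shape:
        raise ValueError("map and mask shapes differ")
    vals = map3d[mask]
    if vals.size < 2:
        raise ValueError("need at least 2 in-mask voxels")
    sd = vals.std()  # population (1/N) convention
    if sd == 0:
        raise ValueError("zero in-mask variance: cannot z-score a constant map")
    out = np.zeros_like(map3d)
    out[mask] = (vals - vals.mean()) / sd
    return out


def _skewness(x: np.ndarray) -> float:
    c = x - x.mean()
    sd = c.std()
    return float(np.mean(c**3) / sd**3) if sd > 0 else 0.0


def _one_unit_polish(
    reduced: np.ndarray,
    sources: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> np.ndarray:
    """Release FastICA's exact-decorrelation constraint per component.

    Symmetric FastICA forces the spatial sources to be exactly
    uncorrelated, but sparse non-overlapping networks are slightly
    anti-correlated over voxels, which leaves a small residual mixing in
    the orthogonal optimum. Starting from the converged solution, each
    unmixing vector is iterated with the one-unit logcosh fixed-point
    update *without* re-orthogonalization, letting every component settle
    on its own contrast maximum. If two components collapse onto the same
    maximum (|r| > 0.9), the symmetric solution is kept instead.
    """
    V, K = reduced.shape
    Xc = reduced.T - reduced.T.mean(axis=1, keepdims=True)  # K x V
    cov = Xc @ Xc.T / V
    lam, vec = np.linalg.eigh(cov)
    if lam[0] <= 0:
        return sources
    XW = ((vec / np.sqrt(lam)) @ vec.T) @ Xc  # whitened, cov = I
    W = XW @ sources / V  # cov I => projection recovers unmixing vectors
    norms = np.linalg.norm(W, axis=0)
    if np.any(norms == 0):
        return sources
    W = W / norms
    for _ in range(max_iter):
        g = np.tanh(W.T @ XW)
        W_new = (XW @ g.T) / V - W * (1 - g**2).mean(axis=1)
        W_new /= np.linalg.norm(W_new, axis=0, keepdims=True)
        delta = np.max(np.abs(np.abs((W_new * W).sum(axis=0)) - 1.0))
        W = W_new
        if delta < tol:
            break
    polished = (W.T @ XW).T  # V x K
    r = np.corrcoef(polished.T)
    if np.any(np.abs(r[~np.eye(K, dtype=bool)]) > 0.9):
        return sources
    return polished


def fit_spatial_ica(
    concatenated: np.ndarray,
    n_components: int,
    mask: np.ndarray,
    seed: int,
    max_iter: int = 1000,
    n_restarts: int = 5,
) -> GroupICs:
    """PCA-reduce the concatenated data and unmix spatially with FastICA.

    The fixed-point iteration uses the logcosh contrast and is restarted
    up to ``n_restarts`` times with derived seeds if it fails to converge.
    Deterministic given ``seed``.
    """
    X = np.asarray(concatenated, dtype=float)
    if X.ndim != 2:
        raise ValueError("concatenated data must be 2D (time x voxels)")
    if n_components > min(X.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(data shape)={min(X.shape)}"
        )
    mask = np.asarray(mask).astype(bool)
    if int(mask.sum()) != X.shape[1]:
        raise ValueError("mask voxel count does not match data columns")

    X = X - X.mean(axis=0, keepdims=True)
    total_var = float(np.sum(X**2))
    if min(X.shape) <= 1500:
        # exact reduction at desk scale; randomized only for large data
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        U, s, Vt = U[:, :n_components], s[:n_components], Vt[:n_components]
    else:
        U, s, Vt = randomized_svd(
            X, n_components=n_components, random_state=child_seed(seed, "pca"),
            n_iter=7,
        )
    explained = s**2 / total_var if total_var > 0 else np.zeros_like(s)

    # ICA operates on the singular-value-scaled spatial PCs (K x V): the
    # sources of interest are spatial, so voxels are the samples.
    Z = (s[:, None] * Vt).T  # V x K
    sources = None
    for attempt in range(n_restarts):
        ica = FastICA(
            n_components=n_components,
            fun="logcosh",
            whiten="unit-variance",
            max_iter=max_iter,
            random_state=child_seed(seed, f"ica-restart{attempt}"),
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            fitted = ica.fit_transform(Z)
            converged = not any(
                issubclass(w.category, ConvergenceWarning) for w in caught
            )
        sources = fitted  # V x K
        if converged:
            break
    else:
        raise RuntimeError(
            f"FastICA did not converge after {n_restarts} restarts of "
            f"{max_iter} iterations each"
        )
    sources = _one_unit_polish(Z, sources)

    maps = np.zeros(mask.shape + (n_components,))
    for k in range(n_components):
        vec = sources[:, k]
        if _skewness(vec) < 0:
            vec = -vec
        flat = np.zeros(mask.shape)
        flat[mask] = vec
        maps[..., k] = zscore_map(flat, mask)

    # Temporal mixing by OLS of the data on the z-scored maps (+ intercept).
    M = maps[mask]  # V x K
    design = np.column_stack([np.ones(M.shape[0]), M])
    coef, *_ = np.linalg.lstsq(design, X.T, rcond=None)
    mixing = coef[1:].T  # sum-T x K

    return GroupICs(maps=maps, mixing=mixing, mask=mask, explained_variance=explained)
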