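"""Temporal preprocessing: nuisance regression and low-frequency retention.

The chain mirrors a standard resting-state recipe: average nuisance
signals over tissue masks, regress motion-like and tissue confounds out of
every in-mask voxel series, then keep only frequencies below the cutoff.
Registration-type steps (slice timing, motion correction, normalization)
are out of scope; inputs are assumed spatially aligned.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .volume import Volume4D

__all__ = [
    "ConfoundMatrix",
    "read_confounds",
    "write_confounds",
    "extract_tissue_signal",
    "regress_out",
    "lowpass_filter",
    "preprocess_subject",
]


@dataclass
class ConfoundMatrix:
    """T x C nuisance regressor matrix with column labels.

    Columns must not be constant after demeaning (an intercept is always
    added internally by :func:`regress_out`, so a constant column would be
    redundant and make the design rank deficient).
    """

    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.names = [str(n) for n in self.names]
        if self.values.ndim != 2:
            raise ValueError("confound values must be a T x C matrix")
        if self.values.shape[1] != len(self.names):
            raise ValueError(
                f"{self.values.shape[1]} columns but {len(self.names)} names"
            )
        demeaned = self.values - self.values.mean(axis=0, keepdims=True)
        constant = np.flatnonzero(np.ptp(demeaned, axis=0) == 0)
        if constant.size:
            raise ValueError(
                f"confound column {self.names[constant[0]]!r} is constant"
            )

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    def appended(self, series: np.ndarray, name: str) -> "ConfoundMatrix":
        series = np.asarray(series, dtype=float).reshape(-1, 1)
        return ConfoundMatrix(
            values=np.hstack([self.values, series]), names=[*self.names, name]
        )


def read_confounds(path: str | os.PathLike) -> ConfoundMatrix:
    """Read a confound TSV (one labelled column per regressor)."""
    if not os.path.exists(path):
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path, sep="\t")
    return ConfoundMatrix(values=df.to_numpy(dtype=float), names=list(df.columns))


def write_confounds(confounds: ConfoundMatrix, path: str | os.PathLike) -> None:
    pd.DataFrame(confounds.values, columns=confounds.names).to_csv(
        path, sep="\t", index=False
    )


def extract_tissue_signal(vol: Volume4D, tissue_mask: np.ndarray) -> np.ndarray:
    """Mean signal over a tissue mask at each time point (length-T vector)."""
    tissue_mask = np.asarray(tissue_mask).astype(bool)
    if tissue_mask.shape != vol.spatial_shape:
        raise ValueError("tissue mask shape does not match volume grid")
    if not tissue_mask.any():
        raise ValueError("empty tissue mask")
    return vol.data[tissue_mask].mean(axis=0)


def _first_dependent_column(X: np.ndarray, names: list[str]) -> str:
    """Name the first column linearly dependent on its predecessors."""
    for j in range(1, X.shape[1]):
        if np.linalg.matrix_rank(X[:, : j + 1]) <= np.linalg.matrix_rank(X[:, :j]):
            return names[j]
    return names[-1]


def regress_out(series_matrix: np.ndarray, confounds: ConfoundMatrix) -> np.ndarray:
    """OLS-residualize every column of a ``(T, V)`` matrix on the confounds.

    An intercept is always included, so residuals are mean zero and
    orthogonal to every demeaned confound column.
    """
    Y = np.asarray(series_matrix, dtype=float)
    squeeze = Y.ndim == 1
    Y = Y.reshape(-1, 1) if squeeze else Y
    T = Y.shape[0]
    if confounds.n_timepoints != T:
        raise ValueError(
            f"confounds have {confounds.n_timepoints} rows but data has {T}"
        )
    X = np.column_stack([np.ones(T), confounds.values])
    names = ["intercept", *confounds.names]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        dep = _first_dependent_column(X, names)
        raise ValueError(f"rank-deficient confounds: column {dep!r} is dependent")
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return resid[:, 0] if squeeze else resid


def lowpass_filter(
    series_matrix: np.ndarray,
    tr_seconds: float,
    cutoff_hz: float,
    kind: str = "ideal",
) -> np.ndarray:
    """Retain frequencies at or below ``cutoff_hz`` along axis 0.

    ``kind="ideal"`` is an FFT-domain brick wall (linear and idempotent;
    DC is retained exactly). ``kind="butterworth"`` is a zero-phase
    order-4 Butterworth alternative.
    """
    Y = np.asarray(series_matrix, dtype=float)
    one_d = Y.ndim == 1
    Y = Y.reshape(-1, 1) if one_d else Y
    T = Y.shape[0]
    nyquist = 1.0 / (2.0 * tr_seconds)
    if cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz at or above Nyquist {nyquist} Hz"
        )
    if kind == "ideal":
        freqs = np.fft.rfftfreq(T, d=tr_seconds)
        spectrum = np.fft.rfft(Y, axis=0)
        spectrum[freqs > cutoff_hz] = 0.0
        out = np.fft.irfft(spectrum, n=T, axis=0)
    elif kind == "butterworth":
        b, a = signal.butter(4, cutoff_hz / nyquist, btype="low")
        out = signal.filtfilt(b, a, Y, axis=0)
    else:
        raise ValueError(f"unknown filter kind: {kind}")
    return out[:, 0] if one_d else out


def preprocess_subject(
    vol: Volume4D,
    confounds: ConfoundMatrix | None = None,
    wm_mask: np.ndarray | None = None,
    csf_mask: np.ndarray | None = None,
    cutoff_hz: float = 0.08,
    filter_kind: str = "ideal",
    filter_confounds_first: bool = False,
) -> Volume4D:
    """Nuisance-regress then low-pass filter one subject's in-mask data.

    White-matter and CSF mean signals (when masks are given) are appended
    to the supplied confounds before regression. ``filter_confounds_first``
    band-limits the confounds before regression to avoid frequency
    mismatch between regressors and the filtered data; off by default to
    follow the stated order (regression, then filtering).
    """
    Y = vol.in_mask_matrix()
    T = vol.n_timepoints
    cm = confounds
    data_scale = float(Y.std()) if Y.size else 0.0
    for mask, label in ((wm_mask, "wm_mean"), (csf_mask, "csf_mean")):
        if mask is not None:
            series = extract_tissue_signal(vol, mask)
            # effectively constant (or already projected out): adds nothing
            if series.std() <= 1e-10 * max(data_scale, 1e-30):
                continue
            if cm is None:
                cm = ConfoundMatrix(values=series.reshape(-1, 1), names=[label])
            else:
                cm = cm.appended(series, label)
    if cm is not None:
        if filter_confounds_first:
            cm = ConfoundMatrix(
                values=lowpass_filter(cm.values, vol.tr_seconds, cutoff_hz, filter_kind),
                names=cm.names,
            )
        Y = regress_out(Y, cm)
    else:
        Y = Y - Y.mean(axis=0, keepdims=True)
    Y = lowpass_filter(Y, vol.tr_seconds, cutoff_hz, kind=filter_kind)
    assert Y.shape == (T, vol.n_voxels)
    return vol.with_in_mask_matrix(Y)
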