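"""Temporal preprocessing of aligned BOLD data.

Order of operations mirrors standard voxel-wise connectivity practice:
extract gray-matter time courses, band-pass filter them to
0.009-0.08 Hz, then regress nuisance signals (6 motion parameters plus
global / white-matter / CSF means) out of the *filtered* series.  The
nuisance regressors are themselves passed through the same filter by
default so the projection acts in-band.

Two zero-phase band-pass implementations are provided:

``fft``
    A hard DFT mask: Fourier coefficients with frequency inside
    [low, high] Hz are kept, all others zeroed.  The measured response
    is exactly 1 in-band and 0 out-of-band at the DFT frequencies.
``butter``
    A second-order Butterworth band-pass applied forward-backward
    (``sosfiltfilt``), i.e. zero phase with a fourth-order magnitude
    response.

The FFT mask is the default; which filter produced a matrix is recorded
in its metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

from .grid import NodeMap
from .synth import BOLDSession, TissueMasks, NuisanceSet

log = logging.getLogger(__name__)


@dataclass
class VoxelMatrix:
    """Time x node matrix of gray-matter voxel time courses."""

    values: np.ndarray            # (t, n_nodes)
    node_map: NodeMap
    tr_seconds: float
    meta: dict = field(default_factory=dict)

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    def with_values(self, values, **meta) -> "VoxelMatrix":
        return VoxelMatrix(values=values, node_map=self.node_map,
                           tr_seconds=self.tr_seconds,
                           meta={**self.meta, **meta})


def extract_gray_timeseries(session: BOLDSession,
                            masks: TissueMasks) -> VoxelMatrix:
    """One column per gray-matter voxel, ordered x-fastest over the grid."""
    if masks.gray.shape != session.grid_shape:
        raise ValueError(
            f"gray mask shape {masks.gray.shape} != session grid "
            f"{session.grid_shape}")
    if not masks.gray.any():
        raise ValueError("gray mask is empty")
    node_map = NodeMap.from_mask(masks.gray, session.affine)
    values = session.data[tuple(node_map.ijk.T)].T.astype(np.float64)
    return VoxelMatrix(values=values, node_map=node_map,
                       tr_seconds=session.tr_seconds,
                       meta={"subject_id": session.subject_id,
                             "condition": session.condition,
                             "session_index": session.session_index})


def _check_band(low_hz, high_hz, tr_seconds):
    nyquist = 1.0 / (2.0 * tr_seconds)
    if not (0.0 <= low_hz < high_hz < nyquist):
        raise ValueError(
            f"band [{low_hz}, {high_hz}] Hz invalid for Nyquist {nyquist} Hz")


def bandpass_series(x: np.ndarray, tr_seconds: float,
                    low_hz: float = 0.009, high_hz: float = 0.08,
                    kind: str = "fft") -> np.ndarray:
    """Zero-phase band-pass along axis 0 of ``x``."""
    _check_band(low_hz, high_hz, tr_seconds)
    x = np.asarray(x, dtype=np.float64)
    if kind == "fft":
        spec = np.fft.rfft(x, axis=0)
        freqs = np.fft.rfftfreq(x.shape[0], d=tr_seconds)
        keep = (freqs >= low_hz) & (freqs <= high_hz)
        spec[~keep] = 0.0
        return np.fft.irfft(spec, n=x.shape[0], axis=0)
    if kind == "butter":
        nyquist = 1.0 / (2.0 * tr_seconds)
        sos = sps.butter(2, [low_hz / nyquist, high_hz / nyquist],
                         btype="bandpass", output="sos")
        return sps.sosfiltfilt(sos, x, axis=0)
    raise ValueError(f"unknown filter kind {kind!r}")


def bandpass(matrix: VoxelMatrix, low_hz: float = 0.009,
             high_hz: float = 0.08, kind: str = "fft") -> VoxelMatrix:
    """Band-pass every voxel time course; the matrix records the filter."""
    out = bandpass_series(matrix.values, matrix.tr_seconds,
                          low_hz, high_hz, kind)
    return matrix.with_values(out, filter=dict(kind=kind, low_hz=low_hz,
                                               high_hz=high_hz))


def _independent_columns(X: np.ndarray, tol: float = 1e-10):
    """Indices of a maximal linearly independent column subset (QR pivoting)."""
    from scipy.linalg import qr
    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    scale = diag[0] if diag.size and diag[0] > 0 else 1.0
    rank = int(np.sum(diag > tol * scale))
    return np.sort(piv[:rank])


def regress_nuisance(matrix: VoxelMatrix, nuisance: NuisanceSet, *,
                     filter_regressors: bool = True,
                     low_hz: Optional[float] = None,
                     high_hz: Optional[float] = None,
                     filter_kind: Optional[str] = None) -> VoxelMatrix:
    """Least-squares residual of each voxel against the nuisance design.

    Design: [intercept, 6 motion, global, white, CSF].  With
    ``filter_regressors`` the nuisance series (not the intercept) are
    passed through the same band-pass the matrix records (or the one
    given explicitly) before projection.  Linearly dependent design
    columns are dropped with a warning.  Zero-variance voxel columns
    pass through unchanged with a warning.
    """
    names, cols = nuisance.design_columns()
    if cols.shape[0] != matrix.n_timepoints:
        raise ValueError(
            f"nuisance length {cols.shape[0]} != time dimension "
            f"{matrix.n_timepoints}")
    if filter_regressors:
        filt = matrix.meta.get("filter", {})
        cols = bandpass_series(
            cols, matrix.tr_seconds,
            low_hz if low_hz is not None else filt.get("low_hz", 0.009),
            high_hz if high_hz is not None else filt.get("high_hz", 0.08),
            filter_kind if filter_kind is not None else filt.get("kind", "fft"))
    X = np.column_stack([np.ones(matrix.n_timepoints), cols])
    names = ["intercept"] + names

    keep = _independent_columns(X)
    if keep.size < X.shape[1]:
        dropped = [names[i] for i in range(X.shape[1]) if i not in keep]
        log.warning("nuisance design rank-deficient; dropping %s", dropped)
        X = X[:, keep]

    Y = matrix.values
    sd = Y.std(axis=0)
    dead = sd == 0
    if dead.any():
        log.warning("%d zero-variance voxel column(s) pass through "
                    "unregressed", int(dead.sum()))
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    if dead.any():
        resid[:, dead] = Y[:, dead]
    return matrix.with_values(resid, nuisance_regressed=True,
                              regressors_filtered=bool(filter_regressors))
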