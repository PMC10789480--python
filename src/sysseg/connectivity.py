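"""From ROI time series to Fisher-z connectivity matrices.

The denoising recipe mirrors a common fMRI ROI pipeline: each ROI signal is
the first temporal eigenvector of its voxel block; slow drifts below a
high-pass cutoff are represented by a discrete-cosine basis; nine nuisance
signals (six rigid-body realignment parameters, white-matter mean, CSF mean,
global mean) are expanded to 36 regressors (raw, backward-difference
derivative, square, squared derivative); high-motion volumes receive one
spike (delta) regressor each.  Drift basis, confounds and spikes are removed
in a single joint least-squares projection, after which Pearson correlations
are Fisher-transformed to z.

An optional Bartlett-style correction rescales z by the effective temporal
degrees of freedom estimated from lag-windowed autocorrelations; plain
``atanh`` is the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateInputError,
    InsufficientDataError,
    SchemaError,
    ValidationError,
)

#: fMRIPrep-dialect names of the nine base nuisance columns, motion first.
BASE_CONFOUND_COLUMNS: tuple[str, ...] = (
    "trans_x",
    "trans_y",
    "trans_z",
    "rot_x",
    "rot_y",
    "rot_z",
    "white_matter",
    "csf",
    "global_signal",
)
MOTION_COLUMNS: tuple[str, ...] = BASE_CONFOUND_COLUMNS[:6]
GLOBAL_SIGNAL_COLUMN = "global_signal"


@dataclass
class ROITimeSeries:
    """One participant/state matrix of ROI signals over time.

    Parameters
    ----------
    values : ndarray, shape (timepoints, rois)
        Signal in arbitrary units; must be finite.
    sampling_interval : float
        Repetition time (TR) in seconds.
    roi_ids : sequence of str
        Unique ROI identifiers, one per column.
    """

    values: np.ndarray
    sampling_interval: float
    roi_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.roi_ids = [str(r) for r in self.roi_ids]
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D (timepoints x ROIs) array")
        if self.values.shape[1] != len(self.roi_ids):
            raise ValidationError(
                f"{self.values.shape[1]} columns but {len(self.roi_ids)} roi_ids"
            )
        if len(set(self.roi_ids)) != len(self.roi_ids):
            raise ValidationError("roi_ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("time series contains non-finite values")
        if self.sampling_interval <= 0:
            raise ValidationError("sampling_interval must be > 0 seconds")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


@dataclass
class ConfoundSet:
    """Nuisance regressors for one run.

    ``base`` holds the nine named columns (six motion parameters, WM, CSF,
    global signal).  ``spike_columns`` is a (timepoints x S) 0/1 matrix with
    exactly one nonzero entry per column.
    """

    base: pd.DataFrame
    spike_columns: np.ndarray | None = None

    def __post_init__(self) -> None:
        missing = [c for c in BASE_CONFOUND_COLUMNS if c not in self.base.columns]
        if missing:
            raise SchemaError(f"confound table missing column(s): {missing}")
        if self.spike_columns is not None:
            self.spike_columns = np.asarray(self.spike_columns, dtype=float)
            if self.spike_columns.size and (
                self.spike_columns.shape[0] != len(self.base)
                or not np.all(self.spike_columns.sum(axis=0) == 1.0)
                or not np.all(np.isin(self.spike_columns, (0.0, 1.0)))
            ):
                raise ValidationError(
                    "each spike column must contain exactly one entry equal to 1"
                )

    @property
    def realignment_params(self) -> np.ndarray:
        return self.base[list(MOTION_COLUMNS)].to_numpy(dtype=float)

    def expanded_design(self, gsr: bool = True) -> pd.DataFrame:
        cols = self.base[list(BASE_CONFOUND_COLUMNS)]
        if not gsr:
            cols = cols.drop(columns=[GLOBAL_SIGNAL_COLUMN])
        return expand_confounds(cols)


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI x ROI matrix of Fisher-z edge weights.

    The diagonal is fixed to zero and excluded from all downstream
    averaging.
    """

    z_values: np.ndarray
    roi_ids: list[str]
    state_label: str = "rest"
    variant: str = "full-correlation|gsr"

    def __post_init__(self) -> None:
        self.z_values = np.asarray(self.z_values, dtype=float)
        self.roi_ids = [str(r) for r in self.roi_ids]
        n = len(self.roi_ids)
        if self.z_values.shape != (n, n):
            raise ValidationError("z_values must be square and match roi_ids")
        off = ~np.eye(n, dtype=bool)
        if not np.all(np.isfinite(self.z_values[off])):
            raise ValidationError("non-finite off-diagonal z values")
        if not np.allclose(self.z_values, self.z_values.T, atol=1e-10):
            raise ValidationError("z_values must be symmetric")
        np.fill_diagonal(self.z_values, 0.0)


def summarize_roi(voxel_block: np.ndarray) -> np.ndarray:
    """First temporal eigenvector of a (timepoints x voxels) block.

    The block is column-centered; the first left singular vector is scaled
    back to signal units (singular value / sqrt(voxels)) and its sign is
    chosen so it correlates non-negatively with the across-voxel mean.
    """
    block = np.asarray(voxel_block, dtype=float)
    if block.ndim == 1:
        block = block[:, None]
    if block.shape[0] < 3 or block.shape[1] < 1:
        raise ValidationError("need >=3 timepoints and >=1 voxel")
    if not np.all(np.isfinite(block)):
        raise ValidationError("voxel block contains non-finite values")
    centered = block - block.mean(axis=0)
    if np.allclose(centered, 0.0):
        raise DegenerateInputError("voxel block is constant in time")
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    ts = u[:, 0] * s[0] / np.sqrt(block.shape[1])
    mean_ts = centered.mean(axis=1)
    if np.dot(ts, mean_ts) < 0:
        ts = -ts
    return ts


def expand_confounds(base: pd.DataFrame) -> pd.DataFrame:
    """Expand base confounds to (raw, derivative, square, squared-derivative).

    The derivative is the backward difference with a leading zero.  Column
    order groups the four variants per base column; names follow the
    fMRIPrep dialect (``_derivative1``, ``_power2``, ``_derivative1_power2``).
    """
    out: dict[str, np.ndarray] = {}
    for name in base.columns:
        col = base[name].to_numpy(dtype=float)
        deriv = np.concatenate(([0.0], np.diff(col)))
        out[name] = col
        out[f"{name}_derivative1"] = deriv
        out[f"{name}_power2"] = col**2
        out[f"{name}_derivative1_power2"] = deriv**2
    return pd.DataFrame(out, index=base.index)


def _detrend_linear(x: np.ndarray) -> np.ndarray:
    t = np.arange(x.shape[0], dtype=float)
    design = np.column_stack([np.ones_like(t), t])
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    return x - design @ beta


def detect_spikes(realignment_params: np.ndarray, k: float = 5.0) -> np.ndarray:
    """Flag high-motion frames.

    Each of the six realignment columns is linearly detrended; the
    per-timepoint motion score is the root mean square across columns.
    Frames whose score exceeds ``mean + k * SD`` of the score series are
    flagged.  Returns the sorted frame indices.
    """
    if k <= 0:
        raise ValidationError("spike threshold multiplier k must be > 0")
    params = np.asarray(realignment_params, dtype=float)
    if params.ndim != 2 or params.shape[0] < 10:
        raise ValidationError("need a (timepoints x 6) array with >=10 timepoints")
    detrended = _detrend_linear(params)
    score = np.sqrt(np.mean(detrended**2, axis=1))
    threshold = score.mean() + k * score.std()
    return np.flatnonzero(score > threshold)


def spike_design(n_timepoints: int, frames: np.ndarray) -> np.ndarray:
    """One delta column per flagged frame."""
    frames = np.asarray(frames, dtype=int)
    design = np.zeros((n_timepoints, frames.size))
    design[frames, np.arange(frames.size)] = 1.0
    return design


def dct_drift_basis(n_timepoints: int, sampling_interval: float, cutoff: float) -> np.ndarray:
    """Discrete-cosine drift regressors spanning periods longer than 1/cutoff.

    Returns a (timepoints x K) matrix of DCT-II basis functions with
    frequencies k / (2 * T * TR) below ``cutoff`` (k >= 1).
    """
    duration = n_timepoints * sampling_interval
    n_basis = int(np.floor(2.0 * cutoff * duration))
    t = np.arange(n_timepoints, dtype=float)
    basis = np.empty((n_timepoints, n_basis))
    for j in range(n_basis):
        basis[:, j] = np.cos(np.pi * (t + 0.5) * (j + 1) / n_timepoints)
    return basis


def highpass_filter(ts: ROITimeSeries, cutoff: float = 0.01) -> ROITimeSeries:
    """Remove frequencies below ``cutoff`` (Hz) via DCT-basis projection.

    The output is mean-centered; inputs already orthogonal to the drift
    basis are returned unchanged up to centering.
    """
    nyquist = 0.5 / ts.sampling_interval
    if cutoff >= nyquist:
        raise ValidationError(f"cutoff {cutoff} Hz is at/above Nyquist {nyquist} Hz")
    basis = dct_drift_basis(ts.n_timepoints, ts.sampling_interval, cutoff)
    centered = ts.values - ts.values.mean(axis=0)
    if basis.shape[1]:
        beta, *_ = np.linalg.lstsq(basis, centered, rcond=None)
        centered = centered - basis @ beta
    return ROITimeSeries(centered, ts.sampling_interval, ts.roi_ids)


def _drop_dependent_columns(design: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """QR with pivoting; returns (reduced design, kept column indices)."""
    from scipy.linalg import qr

    _, r, piv = qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(design.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    keep = np.sort(piv[:rank])
    return design[:, keep], keep


def regress_confounds(ts: ROITimeSeries, design: np.ndarray) -> ROITimeSeries:
    """Least-squares residuals of every ROI series against ``design``.

    Rank-deficient designs are reduced by dropping dependent columns with a
    warning.  Residuals are orthogonal to every retained column.
    """
    design = np.asarray(design, dtype=float)
    if design.ndim != 2 or design.shape[0] != ts.n_timepoints:
        raise ValidationError("design rows must equal timepoints")
    if ts.n_timepoints <= design.shape[1]:
        raise InsufficientDataError(
            f"{ts.n_timepoints} timepoints <= {design.shape[1]} design columns"
        )
    reduced, keep = _drop_dependent_columns(design)
    if keep.size < design.shape[1]:
        warnings.warn(
            f"design rank-deficient: dropped {design.shape[1] - keep.size} "
            "dependent column(s)",
            stacklevel=2,
        )
    beta, *_ = np.linalg.lstsq(reduced, ts.values, rcond=None)
    resid = ts.values - reduced @ beta
    return ROITimeSeries(resid, ts.sampling_interval, ts.roi_ids)


def build_denoising_design(
    ts: ROITimeSeries,
    confounds: ConfoundSet | None,
    *,
    highpass: float | None = 0.01,
    spike_k: float | None = 5.0,
    gsr: bool = True,
    extra_regressors: np.ndarray | None = None,
) -> np.ndarray:
    """Joint design: intercept + DCT drift basis + expanded confounds + spikes.

    Filtering and confound removal happen in one projection so neither step
    can reintroduce variance removed by the other.  ``extra_regressors``
    accepts externally supplied columns (e.g. task regressors).
    """
    parts: list[np.ndarray] = [np.ones((ts.n_timepoints, 1))]
    if highpass is not None:
        nyquist = 0.5 / ts.sampling_interval
        if highpass >= nyquist:
            raise ValidationError(f"cutoff {highpass} Hz is at/above Nyquist {nyquist} Hz")
        parts.append(dct_drift_basis(ts.n_timepoints, ts.sampling_interval, highpass))
    if confounds is not None:
        parts.append(confounds.expanded_design(gsr=gsr).to_numpy(dtype=float))
        if spike_k is not None:
            frames = detect_spikes(confounds.realignment_params, k=spike_k)
            if frames.size:
                parts.append(spike_design(ts.n_timepoints, frames))
        if confounds.spike_columns is not None and confounds.spike_columns.size:
            parts.append(confounds.spike_columns)
    if extra_regressors is not None:
        parts.append(np.asarray(extra_regressors, dtype=float))
    return np.column_stack(parts)


def denoise(
    ts: ROITimeSeries,
    confounds: ConfoundSet | None = None,
    *,
    highpass: float | None = 0.01,
    spike_k: float | None = 5.0,
    gsr: bool = True,
    extra_regressors: np.ndarray | None = None,
) -> ROITimeSeries:
    """High-pass filter and confound regression in one joint projection."""
    design = build_denoising_design(
        ts,
        confounds,
        highpass=highpass,
        spike_k=spike_k,
        gsr=gsr,
        extra_regressors=extra_regressors,
    )
    return regress_confounds(ts, design)


def correlation_matrix(ts: ROITimeSeries) -> np.ndarray:
    """Pearson correlation matrix of the ROI series (diagonal = 1)."""
    if ts.n_timepoints < 3:
        raise InsufficientDataError("need >=3 timepoints for correlation")
    sd = ts.values.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [ts.roi_ids[i] for i in dead]
        raise DegenerateInputError(f"zero-variance ROI(s): {names}")
    r = np.corrcoef(ts.values, rowvar=False)
    return (r + r.T) / 2.0


def _tapered_autocorr(values: np.ndarray, max_lag: int) -> np.ndarray:
    """Per-column autocorrelations to ``max_lag``, Tukey (cosine) tapered."""
    x = values - values.mean(axis=0)
    n = x.shape[0]
    denom = np.sum(x * x, axis=0)
    rho = np.empty((x.shape[1], max_lag + 1))
    rho[:, 0] = 1.0
    for lag in range(1, max_lag + 1):
        rho[:, lag] = np.sum(x[lag:] * x[:-lag], axis=0) / denom
    taper = 0.5 * (1.0 + np.cos(np.pi * np.arange(max_lag + 1) / (max_lag + 1)))
    taper[0] = 1.0
    return rho * np.sqrt(taper)


def effective_dof(values: np.ndarray) -> np.ndarray:
    """Bartlett effective sample size per ROI pair.

    ``T_eff[i, j] = T / (1 + 2 * sum_k w_k rho_i(k) rho_j(k))`` with a Tukey
    taper over lags up to T/3.  White-noise series give T_eff ~ T.
    """
    n = values.shape[0]
    max_lag = max(1, n // 3)
    a = _tapered_autocorr(values, max_lag)
    cross = a[:, 1:] @ a[:, 1:].T
    denom = 1.0 + 2.0 * cross
    denom = np.maximum(denom, 1e-3)
    return np.clip(n / denom, 4.0, float(n))


def fisher_z(
    r: np.ndarray,
    ts_length: int | None = None,
    autocorr_correction: bool = False,
    *,
    timeseries: ROITimeSeries | None = None,
    roi_ids: list[str] | None = None,
    state_label: str = "rest",
    variant: str = "full-correlation|gsr",
) -> ConnectivityMatrix:
    """Fisher r-to-z transform, optionally rescaled by effective dof.

    With the correction off, ``z = atanh(r)``.  With it on,
    ``z = atanh(r) * sqrt(T_eff - 3) / sqrt(T - 3)`` where ``T_eff`` comes
    from :func:`effective_dof` of the residual series (which must be
    supplied via ``timeseries``).
    """
    r = np.asarray(r, dtype=float)
    n = r.shape[0]
    off = ~np.eye(n, dtype=bool)
    if np.any(np.abs(r[off]) >= 1.0):
        raise DegenerateInputError("off-diagonal |r| >= 1: singular edge")
    z = np.zeros_like(r)
    z[off] = np.arctanh(r[off])
    if autocorr_correction:
        if timeseries is None:
            raise ValidationError("autocorr correction requires the residual time series")
        t = ts_length or timeseries.n_timepoints
        t_eff = effective_dof(timeseries.values)
        z = z * np.sqrt(np.maximum(t_eff - 3.0, 1.0)) / np.sqrt(t - 3.0)
        z = (z + z.T) / 2.0
    if roi_ids is None:
        roi_ids = timeseries.roi_ids if timeseries is not None else [
            f"roi{i}" for i in range(n)
        ]
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z, roi_ids, state_label=state_label, variant=variant)


def timeseries_to_connectivity(
    ts: ROITimeSeries,
    confounds: ConfoundSet | None = None,
    *,
    highpass: float | None = 0.01,
    spike_k: float | None = 5.0,
    gsr: bool = True,
    autocorr_correction: bool = False,
    extra_regressors: np.ndarray | None = None,
    state_label: str = "rest",
) -> ConnectivityMatrix:
    """Full stage: joint denoising, Pearson correlation, Fisher z."""
    resid = denoise(
        ts,
        confounds,
        highpass=highpass,
        spike_k=spike_k,
        gsr=gsr,
        extra_regressors=extra_regressors,
    )
    r = correlation_matrix(resid)
    variant = "full-correlation|" + ("gsr" if gsr else "no-gsr")
    return fisher_z(
        r,
        ts_length=resid.n_timepoints,
        autocorr_correction=autocorr_correction,
        timeseries=resid,
        state_label=state_label,
        variant=variant,
    )
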