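"""BOLD run preprocessing: motion metrics, frame censoring, nuisance
regression, grand-mean normalization and band-pass filtering.

The scrubbing pipeline follows the resting-state literature's standard
order: normalize to a grand mean of 1000, compute framewise displacement
(FD) and DVARS, censor frames exceeding either threshold, regress motion
and polynomial drift from each voxel time course on the retained frames,
then band-pass filter with censored frames linearly interpolated before
filtering and re-dropped afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.linalg
from numpy.polynomial import legendre


class PreprocError(ValueError):
    pass


@dataclass
class MotionTrace:
    """Six rigid-body motion parameters per frame.

    ``translations`` are in mm, ``rotations`` in radians; one row per
    BOLD frame.
    """

    translations: np.ndarray  # (T, 3) mm
    rotations: np.ndarray  # (T, 3) radians

    def __post_init__(self) -> None:
        self.translations = np.asarray(self.translations, dtype=float)
        self.rotations = np.asarray(self.rotations, dtype=float)
        if self.translations.shape != self.rotations.shape or self.translations.ndim != 2:
            raise PreprocError("translations and rotations must both be (T, 3)")

    @property
    def n_frames(self) -> int:
        return self.translations.shape[0]


@dataclass
class BoldRun:
    """A 4-D BOLD time series on the common grid.

    ``data`` has shape (X, Y, Z, T).  ``keep`` is the frame-censor mask
    (True = retained); None means no censoring has been applied yet.
    ``norm_target`` records the grand-mean normalization state.
    """

    data: np.ndarray
    tr: float
    run_index: int = 0
    norm_target: float | None = None
    keep: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise PreprocError(f"BOLD data must be 4-D, got shape {self.data.shape}")
        if self.tr <= 0:
            raise PreprocError("TR must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]

    @property
    def shape(self) -> tuple:
        return self.data.shape[:3]


@dataclass
class CensorMask:
    """Per-frame keep/drop flags for one run."""

    keep: np.ndarray  # (T,) bool

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)

    @property
    def n_retained(self) -> int:
        return int(self.keep.sum())

    @property
    def n_frames(self) -> int:
        return self.keep.size


@dataclass
class RetentionReport:
    """Run/subject validity under the frame-retention rules."""

    run_valid: list
    subject_valid: bool
    retained_per_run: list
    total_retained: int


def framewise_displacement(trace: MotionTrace, head_radius_mm: float = 50.0) -> np.ndarray:
    """Framewise displacement in mm.

    FD_t = sum |Delta translation_i| + radius * sum |Delta rotation_i|,
    with rotations converted to arc length at ``head_radius_mm``.  The
    first frame has FD = 0 by convention.
    """
    if trace.n_frames < 2:
        raise PreprocError("framewise displacement requires at least 2 frames")
    dtrans = np.abs(np.diff(trace.translations, axis=0)).sum(axis=1)
    drot = np.abs(np.diff(trace.rotations, axis=0)).sum(axis=1)
    fd = np.concatenate([[0.0], dtrans + head_radius_mm * drot])
    return fd


def dvars(run: BoldRun, mask: np.ndarray) -> np.ndarray:
    """RMS frame-to-frame intensity change over ``mask`` voxels.

    Expressed in the units of the run itself; with mode-1000
    normalization the conventional threshold of 25 corresponds to a 2.5%
    signal change.  The first frame has DVARS = 0.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise PreprocError("dvars: empty mask")
    ts = run.data[mask]  # (V, T)
    diff = np.diff(ts, axis=1)
    out = np.concatenate([[0.0], np.sqrt(np.mean(diff**2, axis=0))])
    return out


def normalize_global(run: BoldRun, target: float = 1000.0, mask: np.ndarray | None = None) -> BoldRun:
    """Scale the run so its in-brain grand mean equals ``target``."""
    if mask is None:
        mask = np.ones(run.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    mean = float(run.data[mask].mean())
    if mean <= 0:
        raise PreprocError(f"normalize_global: nonpositive in-brain mean {mean}")
    return replace(run, data=run.data * (target / mean), norm_target=target)


def censor_frames(
    fd: np.ndarray,
    dvars_tc: np.ndarray,
    fd_thresh: float = 0.2,
    dvars_thresh: float = 25.0,
) -> CensorMask:
    """Drop a frame iff FD > fd_thresh OR DVARS > dvars_thresh.

    Boundary values are kept (strict inequality).
    """
    fd = np.asarray(fd, dtype=float)
    dvars_tc = np.asarray(dvars_tc, dtype=float)
    if fd.shape != dvars_tc.shape:
        raise PreprocError(f"censor_frames: length mismatch {fd.shape} vs {dvars_tc.shape}")
    keep = ~((fd > fd_thresh) | (dvars_tc > dvars_thresh))
    return CensorMask(keep=keep)


def apply_retention_rules(
    masks: list,
    min_run_frames: int = 50,
    min_total_frames: int = 150,
) -> RetentionReport:
    """Discard runs with < min_run_frames retained; exclude the subject
    if valid runs retain < min_total_frames in total."""
    if not masks:
        raise PreprocError("apply_retention_rules: no censor masks given")
    retained = [m.n_retained for m in masks]
    run_valid = [r >= min_run_frames for r in retained]
    total = sum(r for r, v in zip(retained, run_valid) if v)
    return RetentionReport(
        run_valid=run_valid,
        subject_valid=total >= min_total_frames,
        retained_per_run=retained,
        total_retained=total,
    )


def _drift_basis(n_frames: int, order: int) -> np.ndarray:
    """Legendre polynomials up to ``order`` on [-1, 1], one column each."""
    x = np.linspace(-1.0, 1.0, n_frames)
    cols = [legendre.Legendre.basis(k)(x) for k in range(order + 1)]
    return np.column_stack(cols)


def nuisance_design(trace: MotionTrace, drift_order: int = 2) -> tuple:
    """Motion (6 columns) + Legendre drift (order+1 columns) design."""
    names = [f"trans_{ax}" for ax in "xyz"] + [f"rot_{ax}" for ax in "xyz"]
    names += [f"drift_{k}" for k in range(drift_order + 1)]
    X = np.column_stack(
        [trace.translations, trace.rotations, _drift_basis(trace.n_frames, drift_order)]
    )
    return X, names


def nuisance_regress(
    run: BoldRun,
    trace: MotionTrace,
    censor: CensorMask | None = None,
    drift_order: int = 2,
) -> BoldRun:
    """Regress motion parameters and polynomial drift out of each voxel
    time course, fitting on retained frames only.

    Residuals are computed for all frames (so later interpolation acts on
    residualized data) but are exactly orthogonal to the nuisance columns
    over the retained frames.
    """
    X, names = nuisance_design(trace, drift_order)
    keep = censor.keep if censor is not None else np.ones(run.n_frames, dtype=bool)
    if keep.size != run.n_frames:
        raise PreprocError("censor mask length does not match run")
    Xk = X[keep]
    rank = np.linalg.matrix_rank(Xk)
    if rank < Xk.shape[1]:
        # identify offending columns via pivoted QR
        _, _, piv = scipy.linalg.qr(Xk, pivoting=True)
        bad = [names[i] for i in piv[rank:]]
        raise PreprocError(f"nuisance design rank-deficient; collinear columns: {bad}")
    V = int(np.prod(run.shape))
    Y = run.data.reshape(V, run.n_frames).T  # (T, V)
    beta, *_ = np.linalg.lstsq(Xk, Y[keep], rcond=None)
    resid = Y - X @ beta
    out = resid.T.reshape(run.data.shape)
    return replace(run, data=out, keep=keep.copy())


def _interpolate_censored(data2d: np.ndarray, keep: np.ndarray) -> np.ndarray:
    """Linear interpolation across censored frames, per voxel (vectorized:
    the censor pattern is shared across voxels).  Edge frames outside the
    retained range take the nearest retained value."""
    if keep.all():
        return data2d
    T = keep.size
    idx = np.arange(T)
    kept_idx = idx[keep]
    out = data2d.copy()
    # np.interp semantics per frame, built once
    left = np.searchsorted(kept_idx, idx, side="right") - 1
    right = np.searchsorted(kept_idx, idx, side="left")
    left = np.clip(left, 0, kept_idx.size - 1)
    right = np.clip(right, 0, kept_idx.size - 1)
    i0 = kept_idx[left]
    i1 = kept_idx[right]
    w = np.where(i1 > i0, (idx - i0) / np.maximum(i1 - i0, 1), 0.0)
    out = data2d[:, i0] * (1 - w) + data2d[:, i1] * w
    out[:, keep] = data2d[:, keep]
    return out


def bandpass_timecourses(
    data2d: np.ndarray,
    tr: float,
    f_lo: float,
    f_hi: float,
    keep: np.ndarray | None = None,
) -> np.ndarray:
    """Zero-phase FFT band-pass of (V, T) time courses.

    Frequency bins with f_lo <= f <= f_hi are retained (DC always
    removed); censored frames are linearly interpolated before filtering.
    The brick-wall spectral filter makes the band limit exact for
    bin-aligned components and is the conventional choice for short
    resting-state series.
    """
    data2d = np.atleast_2d(np.asarray(data2d, dtype=float))
    T = data2d.shape[1]
    nyq = 0.5 / tr
    if not (0 < f_lo < f_hi < nyq):
        raise PreprocError(f"invalid band [{f_lo}, {f_hi}] for Nyquist {nyq}")
    if keep is not None:
        data2d = _interpolate_censored(data2d, np.asarray(keep, dtype=bool))
    freqs = np.fft.rfftfreq(T, d=tr)
    H = ((freqs >= f_lo) & (freqs <= f_hi)).astype(float)
    H[0] = 0.0
    spec = np.fft.rfft(data2d, axis=1)
    return np.fft.irfft(spec * H, n=T, axis=1)


def bandpass(
    run: BoldRun,
    f_lo: float = 0.009,
    f_hi: float = 0.08,
    censor: CensorMask | None = None,
) -> BoldRun:
    """Band-pass filter a run (default passband 0.009-0.08 Hz).

    Censored frames are interpolated before filtering and re-dropped
    afterwards: the returned run keeps the censor mask so downstream
    operations use retained frames only.
    """
    keep = censor.keep if censor is not None else run.keep
    V = int(np.prod(run.shape))
    flat = run.data.reshape(V, run.n_frames)
    out = bandpass_timecourses(flat, run.tr, f_lo, f_hi, keep=keep)
    return replace(run, data=out.reshape(run.data.shape), keep=None if keep is None else keep.copy())


def effective_frames(n_frames: int, tr: float, f_lo: float, f_hi: float) -> float:
    """Effective number of independent frames after band-pass filtering.

    For a linear filter with power transfer |H|^2, the variance inflation
    of a sample correlation between two identically filtered white series
    is sum_k rho(k)^2 = n * sum|H|^4 / (sum|H|^2)^2 (Bartlett), giving
    n_eff = (sum|H|^2)^2 / sum|H|^4 over the full two-sided spectrum.
    For the brick-wall filter this equals the number of retained Fourier
    bins counting both spectral sides.
    """
    freqs = np.fft.rfftfreq(n_frames, d=tr)
    Hsq = ((freqs >= f_lo) & (freqs <= f_hi)).astype(float)
    Hsq[0] = 0.0
    w = np.full(freqs.size, 2.0)
    w[0] = 1.0
    if n_frames % 2 == 0:
        w[-1] = 1.0
    s2 = float((w * Hsq).sum())
    s4 = float((w * Hsq**2).sum())
    if s4 == 0:
        raise PreprocError("empty passband")
    return s2 * s2 / s4
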