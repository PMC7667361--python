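"""Temporal preprocessing of BOLD series.

Stages, in the fixed order used by the pipeline: discard of initial
volumes (magnetic-saturation dummies), per-voxel linear detrending plus
band-pass filtering (0.01-0.1 Hz), and nuisance regression with the
24-parameter Friston motion model (plus optional tissue signals). Head
motion is summarized as Jenkinson's frame-wise displacement (FD), an RMS
displacement over an 80 mm sphere, and screened against translation /
rotation exclusion limits.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .types import BoldSeries, check_motion_trace

log = logging.getLogger(__name__)

#: Default number of initial volumes dropped to skip magnetic-saturation
#: transients.
N_DISCARD_DEFAULT = 10

#: Default pass band (Hz) isolating low-frequency BOLD fluctuations.
BAND_DEFAULT = (0.01, 0.1)


# ---------------------------------------------------------------------------
# volume discarding
# ---------------------------------------------------------------------------

def discard_initial(series: BoldSeries, n_discard: int = N_DISCARD_DEFAULT) -> BoldSeries:
    """Drop the first ``n_discard`` volumes of a series."""
    if n_discard < 0:
        raise ValueError("n_discard must be >= 0")
    if series.n_volumes <= n_discard:
        raise ValueError(
            f"cannot discard {n_discard} volumes from a series of "
            f"{series.n_volumes} volumes"
        )
    if n_discard == 0:
        return series.copy_with(series.data.copy())
    return series.copy_with(series.data[..., n_discard:].copy())


# ---------------------------------------------------------------------------
# band-pass filtering
# ---------------------------------------------------------------------------

def bandpass_weights(
    n: int, dt: float, low: float, high: float, taper: float = 0.004
) -> np.ndarray:
    """Frequency-domain weights of the zero-phase band-pass filter.

    A rectangular pass band ``[low, high]`` with raised-cosine transition
    bands of total width ``taper`` (Hz) centred on each edge. The DC bin
    is always zero, so filtered output is mean-free.
    """
    freqs = np.fft.rfftfreq(n, d=dt)
    w = np.zeros_like(freqs)
    lo0, lo1 = low - taper / 2.0, low + taper / 2.0
    hi0, hi1 = high - taper / 2.0, high + taper / 2.0
    w[(freqs >= lo1) & (freqs <= hi0)] = 1.0
    if taper > 0:
        rise = (freqs > lo0) & (freqs < lo1)
        w[rise] = 0.5 * (1.0 - np.cos(np.pi * (freqs[rise] - lo0) / taper))
        fall = (freqs > hi0) & (freqs < hi1)
        w[fall] = 0.5 * (1.0 + np.cos(np.pi * (freqs[fall] - hi0) / taper))
    w[freqs == 0.0] = 0.0
    return w


def bandpass_array(
    arr: np.ndarray,
    tr: float,
    low: float = BAND_DEFAULT[0],
    high: float = BAND_DEFAULT[1],
    taper: float = 0.004,
) -> np.ndarray:
    """Zero-phase band-pass along the last axis via an rFFT mask."""
    nyquist = 0.5 / tr
    if not (0.0 <= low < high):
        raise ValueError(f"need 0 <= low < high, got low={low}, high={high}")
    if high >= nyquist:
        raise ValueError(f"high={high} Hz is at or above Nyquist ({nyquist} Hz) for tr={tr} s")
    n = arr.shape[-1]
    w = bandpass_weights(n, tr, low, high, taper)
    spec = np.fft.rfft(arr, axis=-1)
    spec *= w
    return np.fft.irfft(spec, n=n, axis=-1)


def bandpass_detrend(
    series: BoldSeries,
    low: float = BAND_DEFAULT[0],
    high: float = BAND_DEFAULT[1],
    taper: float = 0.004,
) -> BoldSeries:
    """Per-voxel linear detrend followed by zero-phase band-pass filtering.

    Output voxel series are mean-free (the filter's DC weight is zero).
    """
    data = np.asarray(series.data, dtype=np.float64)
    detrended = sps.detrend(data, axis=-1, type="linear")
    filtered = bandpass_array(detrended, series.tr, low, high, taper)
    return series.copy_with(filtered.astype(np.float32, copy=False))


# ---------------------------------------------------------------------------
# nuisance regression
# ---------------------------------------------------------------------------

def build_friston24(motion: np.ndarray, lag_padding: str = "zero") -> np.ndarray:
    """24-parameter Friston motion regressors.

    Columns are ``[p(t), p(t-1), p(t)^2, p(t-1)^2]`` for each of the six
    rigid-body parameters. The lagged row at t = 0 is zero-padded by
    default (``lag_padding='zero'``); ``lag_padding='repeat'`` repeats the
    first row instead.
    """
    motion = check_motion_trace(motion)
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 volumes for the lagged Friston model")
    lagged = np.vstack([np.zeros((1, 6)), motion[:-1]])
    if lag_padding == "repeat":
        lagged[0] = motion[0]
    elif lag_padding != "zero":
        raise ValueError(f"unknown lag_padding {lag_padding!r}")
    return np.hstack([motion, lagged, motion**2, lagged**2])


@dataclass
class NuisanceModel:
    """Nuisance regressors for one subject.

    ``friston24`` is the (volumes x 24) motion-regressor block;
    ``tissue_signals`` an optional (volumes x m) block of mean white-matter
    / CSF series. Either block may be disabled via its include flag.
    """

    friston24: np.ndarray | None = None
    tissue_signals: np.ndarray | None = None
    include_friston: bool = True
    include_tissue: bool = True

    def matrix(self) -> np.ndarray:
        blocks = []
        if self.include_friston and self.friston24 is not None:
            fr = np.asarray(self.friston24, dtype=float)
            if fr.ndim != 2 or fr.shape[1] != 24:
                raise ValueError(f"friston24 block must have 24 columns, got {fr.shape}")
            blocks.append(fr)
        if self.include_tissue and self.tissue_signals is not None:
            ts = np.atleast_2d(np.asarray(self.tissue_signals, dtype=float))
            if ts.shape[0] == 1 and ts.shape[1] != 1:  # a single row vector
                ts = ts.T
            blocks.append(ts)
        if not blocks:
            return np.empty((0, 0))
        mat = np.hstack(blocks)
        if not np.all(np.isfinite(mat)):
            raise ValueError("nuisance regressors contain non-finite values")
        return mat


def _prune_design(design: np.ndarray, rcond: float = 1e-8) -> tuple[np.ndarray, list[int]]:
    """Drop degenerate (constant or collinear) columns via pivoted QR."""
    from scipy.linalg import qr

    if design.shape[1] == 0:
        return design, []
    _, r, piv = qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = rcond * (diag[0] if diag.size else 0.0)
    keep_rank = int(np.sum(diag > tol))
    kept = sorted(piv[:keep_rank])
    dropped = sorted(piv[keep_rank:])
    return design[:, kept], list(dropped)


def regress_nuisance(series: BoldSeries, model: NuisanceModel) -> BoldSeries:
    """Residualize every voxel on ``[intercept | nuisance columns]`` (OLS).

    Degenerate nuisance columns (all-zero, constant, or collinear) are
    dropped with a logged warning rather than failing the fit.
    """
    nuis = model.matrix()
    n_vol = series.n_volumes
    if nuis.size and nuis.shape[0] != n_vol:
        raise ValueError(
            f"nuisance model has {nuis.shape[0]} rows but series has {n_vol} volumes"
        )
    if nuis.size:
        centered = nuis - nuis.mean(axis=0)
        pruned, dropped = _prune_design(centered)
        if dropped:
            log.warning("dropping %d degenerate nuisance column(s): %s", len(dropped), dropped)
    else:
        pruned = np.empty((n_vol, 0))
    design = np.hstack([np.ones((n_vol, 1)), pruned])
    data = np.asarray(series.data, dtype=np.float64)
    flat = data.reshape(-1, n_vol).T  # volumes x voxels
    beta, *_ = np.linalg.lstsq(design, flat, rcond=None)
    resid = flat - design @ beta
    return series.copy_with(resid.T.reshape(data.shape).astype(np.float32, copy=False))


# ---------------------------------------------------------------------------
# head motion
# ---------------------------------------------------------------------------

def rigid_transform(params: np.ndarray) -> np.ndarray:
    """4x4 rigid-body transform from ``(tx, ty, tz, rx, ry, rz)``.

    Rotations are in radians, applied as ``Rx @ Ry @ Rz`` about the world
    axes, followed by translation.
    """
    tx, ty, tz, rx, ry, rz = np.asarray(params, dtype=float)
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    rot_x = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    rot_y = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rot_z = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    out = np.eye(4)
    out[:3, :3] = rot_x @ rot_y @ rot_z
    out[:3, 3] = (tx, ty, tz)
    return out


@dataclass
class FDSeries:
    """Frame-wise displacement per adjacent volume pair, plus its mean."""

    fd: np.ndarray
    mean_fd: float

    def __post_init__(self) -> None:
        self.fd = np.asarray(self.fd, dtype=float)


def framewise_displacement(motion: np.ndarray, head_radius: float = 80.0) -> FDSeries:
    """Jenkinson frame-wise displacement of a rigid-body motion trace.

    For each adjacent volume pair the relative transform is written as
    ``I + [A b]`` and summarized as the RMS displacement of points on a
    sphere of ``head_radius`` mm:

        FD = sqrt( (1/5) R^2 trace(A^T A) + b^T b )
    """
    motion = check_motion_trace(motion)
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 volumes to compute FD")
    mats = np.stack([rigid_transform(p) for p in motion])
    fd = np.empty(motion.shape[0] - 1)
    for i in range(1, motion.shape[0]):
        rel = mats[i] @ np.linalg.inv(mats[i - 1]) - np.eye(4)
        a = rel[:3, :3]
        b = rel[:3, 3]
        fd[i - 1] = np.sqrt(head_radius**2 / 5.0 * np.sum(a * a) + b @ b)
    return FDSeries(fd=fd, mean_fd=float(fd.mean()))


@dataclass
class ExclusionResult:
    """Outcome of the head-motion screen."""

    passed: bool
    reason: str | None = None

    def __bool__(self) -> bool:  # allows `if motion_exclusion(...)`
        return self.passed


def motion_exclusion(
    motion: np.ndarray, trans_limit: float = 2.0, rot_limit_deg: float = 2.0
) -> ExclusionResult:
    """Screen a trace against the translation / rotation exclusion limits.

    Displacements are measured relative to the first retained volume and
    the limits are strict (a subject moving exactly 2 mm fails).
    """
    motion = check_motion_trace(motion)
    rel = motion - motion[0]
    rot_limit = np.deg2rad(rot_limit_deg)
    axes = "xyz"
    for vol, row in enumerate(rel):
        for ax in range(3):
            if abs(row[ax]) >= trans_limit:
                return ExclusionResult(
                    False,
                    f"translation |{axes[ax]}| = {abs(row[ax]):.3f} mm >= "
                    f"{trans_limit} mm at volume {vol}",
                )
            if abs(row[3 + ax]) >= rot_limit:
                return ExclusionResult(
                    False,
                    f"rotation |{axes[ax]}| = {np.rad2deg(abs(row[3 + ax])):.3f} deg >= "
                    f"{rot_limit_deg} deg at volume {vol}",
                )
    return ExclusionResult(True)


def preprocess_subject(
    series: BoldSeries,
    motion: np.ndarray,
    n_discard: int = N_DISCARD_DEFAULT,
    low: float = BAND_DEFAULT[0],
    high: float = BAND_DEFAULT[1],
    tissue_signals: np.ndarray | None = None,
    filter_regressors: bool = True,
) -> tuple[BoldSeries, FDSeries]:
    """Full temporal preprocessing of one subject.

    Order: discard -> detrend + band-pass -> nuisance regression
    (Friston-24 from the retained motion rows, plus optional tissue
    signals). Nuisance regressors are passed through the same band-pass
    before regression (``filter_regressors``), so regression cannot
    reintroduce out-of-band variance. FD is computed on the retained
    motion rows.
    """
    motion = check_motion_trace(motion)
    if motion.shape[0] != series.n_volumes:
        raise ValueError(
            f"motion trace has {motion.shape[0]} rows for {series.n_volumes} volumes"
        )
    series = discard_initial(series, n_discard)
    motion_kept = motion[n_discard:]
    filtered = bandpass_detrend(series, low, high)
    friston = build_friston24(motion_kept)
    tissue = tissue_signals
    if filter_regressors:
        friston = bandpass_array(friston.T, series.tr, low, high).T
        if tissue is not None:
            tissue = bandpass_array(np.asarray(tissue, dtype=float).T, series.tr, low, high).T
    model = NuisanceModel(friston24=friston, tissue_signals=tissue)
    cleaned = regress_nuisance(filtered, model)
    return cleaned, framewise_displacement(motion_kept)
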