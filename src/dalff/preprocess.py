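"""BOLD preprocessing: volume discarding, motion QC, nuisance regression, smoothing.

Implements the denoising steps that feed the windowed-amplitude analysis:
dropping initial equilibration volumes, excluding subjects whose head
motion exceeds translation/rotation limits, expanding realignment
parameters to the 24-regressor (Friston) model, voxelwise OLS nuisance
regression (with optional linear trend and global mean signal), and
isotropic Gaussian spatial smoothing specified as FWHM in world mm.

Slice-timing correction, realignment and spatial normalization are out of
scope; inputs are assumed already in a common grid.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import MotionParams, VolumeSeries

__all__ = [
    "QCResult",
    "discard_initial",
    "motion_qc",
    "friston24",
    "nuisance_regress",
    "gaussian_smooth",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class QCResult:
    """Outcome of a motion quality check for one subject."""

    passed: bool
    max_translation_mm: np.ndarray  # per axis (x, y, z)
    max_rotation_deg: np.ndarray  # per axis (pitch, roll, yaw)


def discard_initial(
    series: VolumeSeries,
    n_discard: int,
    motion: MotionParams | None = None,
) -> VolumeSeries | tuple[VolumeSeries, MotionParams]:
    """Drop the first ``n_discard`` frames (scanner equilibration).

    If a motion table is supplied its first rows are dropped in lockstep
    and the trimmed pair is returned.
    """
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    if n_discard >= series.n_timepoints:
        raise ValueError(
            f"cannot discard {n_discard} of {series.n_timepoints} frames"
        )
    out = series.with_data(series.data[..., n_discard:])
    if motion is None:
        return out
    if motion.n_timepoints != series.n_timepoints:
        raise ValueError("motion table length does not match series")
    return out, MotionParams(motion.table[n_discard:])


def motion_qc(
    motion: MotionParams,
    trans_limit_mm: float = 2.0,
    rot_limit_deg: float = 2.0,
) -> QCResult:
    """Pass/fail head-motion check with per-axis maxima.

    Fails only on *strictly* greater motion (translation > limit or
    rotation > limit), so a subject at exactly the limit is retained.
    """
    if trans_limit_mm <= 0 or rot_limit_deg <= 0:
        raise ValueError("limits must be positive")
    max_t = np.abs(motion.translations_mm).max(axis=0)
    max_r = np.abs(motion.rotations_deg).max(axis=0)
    passed = bool((max_t <= trans_limit_mm).all() and (max_r <= rot_limit_deg).all())
    return QCResult(passed=passed, max_translation_mm=max_t, max_rotation_deg=max_r)


def friston24(motion: MotionParams) -> np.ndarray:
    """Expand 6 realignment parameters to the 24-regressor motion model.

    Columns are ``[R(t), R(t-1), R(t)^2, R(t-1)^2]`` for the six
    parameters; the lag-1 block uses a zero first row.
    """
    r = motion.table
    if r.shape[0] < 2:
        raise ValueError("need at least two timepoints")
    r_lag = np.vstack([np.zeros((1, 6)), r[:-1]])
    return np.hstack([r, r_lag, r**2, r_lag**2])


def _design_matrix(
    n_timepoints: int,
    regressors: np.ndarray | None,
    add_linear_trend: bool,
    global_signal: np.ndarray | None,
) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = [np.ones(n_timepoints)]
    names = ["intercept"]
    if add_linear_trend:
        cols.append(np.linspace(-1.0, 1.0, n_timepoints))
        names.append("trend")
    if global_signal is not None:
        cols.append(global_signal)
        names.append("global")
    if regressors is not None:
        regressors = np.atleast_2d(np.asarray(regressors, dtype=float))
        if regressors.shape[0] != n_timepoints:
            raise ValueError("regressor rows must match timepoint count")
        cols.extend(regressors.T)
        names.extend(f"reg{i}" for i in range(regressors.shape[1]))
    return np.column_stack(cols), names


def nuisance_regress(
    series: VolumeSeries,
    regressors: np.ndarray | None = None,
    add_linear_trend: bool = True,
    add_global_signal: bool = True,
) -> VolumeSeries:
    """Voxelwise OLS residuals against nuisance covariates.

    The design is ``[intercept | trend? | global mean? | regressors]``;
    the global signal is the per-frame mean over the analysis mask.
    Residuals are exactly orthogonal to every design column.
    """
    t = series.n_timepoints
    gs = None
    if add_global_signal:
        gs = series.data[series.mask].mean(axis=0)
        gs = gs - gs.mean()
    design, names = _design_matrix(t, regressors, add_linear_trend, gs)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns by incremental rank growth
        bad = []
        r_prev = 0
        for j in range(design.shape[1]):
            r_now = np.linalg.matrix_rank(design[:, : j + 1])
            if r_now == r_prev:
                bad.append(names[j])
            r_prev = r_now
        raise ValueError(f"rank-deficient nuisance design; collinear columns: {bad}")
    y = series.data[series.mask].T  # (t, n_voxels)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    out = np.zeros_like(series.data)
    out[series.mask] = resid.T
    return series.with_data(out)


def gaussian_smooth(series: VolumeSeries, fwhm_mm: float) -> VolumeSeries:
    """Per-frame isotropic Gaussian smoothing, FWHM given in world mm.

    The kernel sigma is ``fwhm / (2*sqrt(2*ln 2))`` mm, converted to voxel
    units per axis (anisotropic voxels are handled per-axis).
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm_mm == 0:
        return series.with_data(series.data.copy())
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / series.voxel_size_mm
    out = ndimage.gaussian_filter(
        series.data, sigma=tuple(sigma_vox) + (0.0,), mode="nearest"
    )
    return series.with_data(out)
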