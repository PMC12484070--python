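"""Windowed spectral amplitude: ALFF, sliding-window ALFF, and its temporal CV.

ALFF (amplitude of low-frequency fluctuations) is the mean of the
square-root power spectrum of a BOLD series over a low-frequency band,
conventionally 0.01-0.1 Hz. Dynamic ALFF (dALFF) recomputes ALFF inside
sliding windows and summarizes each voxel's window-to-window variability
by the temporal coefficient of variation, CV = SD / mean (sample SD,
n - 1 denominator).

The periodogram uses a rectangular window (no taper) with optional linear
detrending per segment; in-band bins are the exact DFT frequencies
``k / (N * tr)`` inside the closed interval ``[f_lo, f_hi]``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .volume import VolumeSeries

__all__ = [
    "WindowSpec",
    "BandSpec",
    "DalffMaps",
    "n_windows",
    "alff",
    "sliding_window_alff",
    "dalff_cv",
    "standardize_map",
]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in TR units."""

    length_tr: int
    step_tr: int = 2

    def __post_init__(self) -> None:
        if not (1 <= self.step_tr <= self.length_tr):
            raise ValueError("require 1 <= step_tr <= length_tr")


@dataclass(frozen=True)
class BandSpec:
    """Closed frequency interval [f_lo, f_hi] in Hz."""

    f_lo: float = 0.01
    f_hi: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError("require 0 < f_lo < f_hi")

    def validate_for(self, tr: float) -> None:
        nyquist = 1.0 / (2.0 * tr)
        if self.f_hi > nyquist + 1e-12:
            raise ValueError(
                f"band upper edge {self.f_hi} Hz exceeds Nyquist {nyquist:.4g} Hz"
            )


@dataclass
class DalffMaps:
    """Per-voxel mean, SD and CV of windowed ALFF for one subject."""

    mean_map: np.ndarray
    sd_map: np.ndarray
    cv_map: np.ndarray
    n_windows: int
    window: WindowSpec
    band: BandSpec
    mask: np.ndarray
    standardized: bool = False


def n_windows(n_timepoints: int, window: WindowSpec) -> int:
    """Number of sliding windows: floor((T - length)/step) + 1."""
    if window.length_tr > n_timepoints:
        raise ValueError("window longer than series")
    return (n_timepoints - window.length_tr) // window.step_tr + 1


def band_bins(n: int, tr: float, band: BandSpec) -> np.ndarray:
    """Boolean selector over one-sided DFT frequencies k/(n*tr)."""
    freqs = np.fft.rfftfreq(n, d=tr)
    return (freqs >= band.f_lo - 1e-12) & (freqs <= band.f_hi + 1e-12)


def _detrend_projector(n: int) -> np.ndarray:
    """Residual-maker matrix removing intercept and linear trend."""
    x = np.column_stack([np.ones(n), np.arange(n, dtype=float)])
    return np.eye(n) - x @ np.linalg.pinv(x)


def _alff_segments(
    segments: np.ndarray, tr: float, band: BandSpec, detrend: bool
) -> np.ndarray:
    """ALFF over the last axis of ``segments``; returns amplitude maps.

    Power is expressed as single-sinusoid amplitude (2|F_k|/N), so a pure
    in-band sinusoid of amplitude A at an exact DFT frequency contributes
    A to its bin. ALFF is the mean of sqrt-power over in-band bins.
    """
    n = segments.shape[-1]
    sel = band_bins(n, tr, band)
    if not sel.any():
        warnings.warn(
            f"no DFT frequency in band [{band.f_lo}, {band.f_hi}] Hz at "
            f"resolution {1.0 / (n * tr):.4g} Hz; ALFF is 0",
            RuntimeWarning,
            stacklevel=3,
        )
        return np.zeros(segments.shape[:-1])
    if detrend:
        segments = segments @ _detrend_projector(n).T
    spec = np.abs(np.fft.rfft(segments, axis=-1)) * (2.0 / n)
    return spec[..., sel].mean(axis=-1)


def alff(
    series_1d: np.ndarray,
    tr: float,
    band: BandSpec | None = None,
    detrend: bool = True,
) -> float:
    """ALFF of a single time series."""
    x = np.asarray(series_1d, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ValueError("need a 1D series of length >= 4")
    if np.isnan(x).any():
        raise ValueError("NaN in input series")
    band = band or BandSpec()
    band.validate_for(tr)
    return float(_alff_segments(x[None, :], tr, band, detrend)[0])


def sliding_window_alff(
    series: VolumeSeries,
    window: WindowSpec,
    band: BandSpec | None = None,
    detrend: bool = True,
) -> np.ndarray:
    """Per-window ALFF maps, shape (x, y, z, n_windows).

    Window ``w`` covers timepoints ``[w*step, w*step + length)``. Raises if
    no DFT frequency of the window length falls inside the band.
    """
    band = band or BandSpec()
    band.validate_for(series.tr)
    t = series.n_timepoints
    w = n_windows(t, window)
    n = window.length_tr
    if not band_bins(n, series.tr, band).any():
        raise ValueError(
            f"no in-band frequency bin for window length {n} TR; achievable "
            f"resolution is {1.0 / (n * series.tr):.4g} Hz"
        )
    out = np.zeros(series.spatial_shape + (w,))
    data = series.data[series.mask]  # (n_voxels, t)
    proj = _detrend_projector(n).T if detrend else None
    vals = np.empty((data.shape[0], w))
    for i in range(w):
        seg = data[:, i * window.step_tr : i * window.step_tr + n]
        if proj is not None:
            seg = seg @ proj
        vals[:, i] = _alff_segments(seg, series.tr, band, detrend=False)
    out[series.mask] = vals
    return out


def dalff_cv(
    window_stack: np.ndarray,
    window: WindowSpec,
    band: BandSpec | None = None,
    mask: np.ndarray | None = None,
) -> DalffMaps:
    """Mean, sample SD and CV over the window axis of an ALFF stack.

    Voxels whose mean windowed ALFF is zero have undefined CV (NaN) and
    are removed from the output mask.
    """
    stack = np.asarray(window_stack, dtype=float)
    if stack.ndim != 4:
        raise ValueError("window stack must be 4D (x, y, z, n_windows)")
    w = stack.shape[-1]
    if w < 2:
        raise ValueError("need at least two windows for a CV")
    if mask is None:
        mask = np.ones(stack.shape[:3], dtype=bool)
    mean = stack.mean(axis=-1)
    sd = stack.std(axis=-1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    out_mask = mask & (mean > 0)
    return DalffMaps(
        mean_map=mean,
        sd_map=sd,
        cv_map=cv,
        n_windows=w,
        window=window,
        band=band or BandSpec(),
        mask=out_mask,
    )


def standardize_map(
    map_3d: np.ndarray, mask: np.ndarray, mode: str = "zscore"
) -> np.ndarray:
    """Standardize a 3D map within a mask.

    ``zscore``: subtract the in-mask mean and divide by the in-mask SD.
    ``mean_divide``: divide by the in-mask mean. Out-of-mask voxels are
    set to zero.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    vals = np.asarray(map_3d, dtype=float)[mask]
    out = np.zeros_like(np.asarray(map_3d, dtype=float))
    if mode == "zscore":
        sd = vals.std()
        if sd == 0:
            raise ValueError("zero in-mask SD; z-scoring undefined")
        out[mask] = (vals - vals.mean()) / sd
    elif mode == "mean_divide":
        m = vals.mean()
        if m == 0:
            raise ValueError("zero in-mask mean; mean-division undefined")
        out[mask] = vals / m
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out


def standardize_dalff(maps: DalffMaps, mode: str = "zscore") -> DalffMaps:
    """Return a copy with the CV map standardized within its mask."""
    cv = np.where(maps.mask, np.nan_to_num(maps.cv_map), 0.0)
    return replace(maps, cv_map=standardize_map(cv, maps.mask, mode), standardized=True)
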