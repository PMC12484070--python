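"""Two-group voxelwise inference with cluster-level multiple-comparison control.

The group model is a per-voxel OLS of the subject map on
``[intercept, group, covariates]``; the reported statistic is the t of
the group coefficient. Cluster correction follows Gaussian-random-field
(GRF) theory: the t-field is Gaussianized (probit transform of tail
probabilities), residual-based smoothness (per-axis FWHM, resel count) is
estimated from spatial first differences of the standardized residuals,
and each suprathreshold cluster receives a corrected p from the expected
Euler characteristic / cluster-extent formulae. A Freedman-Lane
permutation scheme provides a nonparametric oracle for the same decision.

Also houses the printed-table demographics statistics (pooled two-sample
t from summary statistics, Pearson chi-square on a 2x2 table) and parcel
averaging of statistic maps.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .parcellation import Parcellation

__all__ = [
    "TStatMap",
    "SmoothnessEstimate",
    "glm_group_t",
    "summary_two_sample_t",
    "chi_square_2x2",
    "estimate_smoothness",
    "grf_cluster_correct",
    "permutation_cluster_correct",
    "parcel_average",
]

CLUSTER_COLUMNS = ["label", "n_voxels", "x_mm", "y_mm", "z_mm", "peak_t", "p_corrected"]
_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class TStatMap:
    """Voxelwise t statistic with its degrees of freedom and mask."""

    t: np.ndarray
    df: int
    mask: np.ndarray


@dataclass(frozen=True)
class SmoothnessEstimate:
    """Per-axis smoothness (FWHM, mm) and resel count of a residual field."""

    fwhm_mm: np.ndarray
    resels: float


def _group_design(design: pd.DataFrame, group_col: str, covariates: list[str]):
    g = design[group_col].to_numpy(dtype=float)
    if len(np.unique(g)) != 2:
        raise ValueError("group column must have exactly two levels")
    g = (g == g.max()).astype(float)
    if g.sum() < 2 or (1 - g).sum() < 2:
        raise ValueError("need at least two subjects per group")
    cols = [np.ones(len(g)), g]
    names = ["intercept", group_col]
    for c in covariates:
        v = design[c].to_numpy(dtype=float)
        if np.isnan(v).any():
            raise ValueError(f"missing values in covariate {c!r}")
        cols.append(v - v.mean())
        names.append(c)
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError(f"rank-deficient group design; columns {names}")
    return x, names


def glm_group_t(
    maps: np.ndarray,
    design: pd.DataFrame,
    group_col: str = "group",
    covariates: list[str] | None = None,
    mask: np.ndarray | None = None,
) -> tuple[TStatMap, np.ndarray]:
    """Voxelwise group-difference t with covariates; returns residuals too.

    ``maps`` is (n_subjects, x, y, z). The group indicator is coded 0/1
    (highest level = 1), covariates are mean-centered; t > 0 means the
    coded-1 group has the larger adjusted mean. Zero-variance voxels get
    NaN and are dropped from the output mask. Residuals (n_subjects, x, y,
    z) feed smoothness estimation.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 4:
        raise ValueError("maps must be (n_subjects, x, y, z)")
    n = maps.shape[0]
    if len(design) != n:
        raise ValueError("design rows must match subject count")
    x, _ = _group_design(design, group_col, covariates or [])
    if mask is None:
        mask = np.ones(maps.shape[1:], dtype=bool)
    y = maps[:, mask]  # (n, V)
    pinv = np.linalg.pinv(x)
    beta = pinv @ y
    resid = y - x @ beta
    df = n - x.shape[1]
    if df < 1:
        raise ValueError("non-positive residual degrees of freedom")
    sigma2 = (resid**2).sum(axis=0) / df
    xtx_inv = np.linalg.inv(x.T @ x)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    # voxels constant across subjects have no error variance: t undefined
    defined = (se > 0) & (y.var(axis=0) > np.finfo(float).eps * (y**2).mean(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(defined, beta[1] / se, np.nan)
    t_map = np.zeros(maps.shape[1:])
    t_map[mask] = tvals
    out_mask = mask.copy()
    out_mask[mask] = defined
    resid_maps = np.zeros_like(maps)
    resid_maps[:, mask] = resid
    return TStatMap(t=t_map, df=df, mask=out_mask), resid_maps


def summary_two_sample_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int]:
    """Pooled-variance two-sample t from summary statistics.

    ``t = (m1 - m2) / (s_p * sqrt(1/n1 + 1/n2))`` with the pooled SD
    ``s_p^2 = ((n1-1) sd1^2 + (n2-1) sd2^2) / (n1 + n2 - 2)``;
    df = n1 + n2 - 2.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be non-negative")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    diff = mean1 - mean2
    if sp2 == 0:
        return (0.0 if diff == 0 else math.copysign(math.inf, diff)), df
    t = diff / (math.sqrt(sp2) * math.sqrt(1.0 / n1 + 1.0 / n2))
    return t, df


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, int]:
    """Pearson chi-square on a 2x2 table, no continuity correction.

    ``chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))``, df = 1.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if n == 0 or 0 in margins:
        raise ValueError("zero margin; chi-square undefined")
    chi2 = n * (a * d - b * c) ** 2 / math.prod(margins)
    return float(chi2), 1


def estimate_smoothness(
    residuals: np.ndarray,
    mask: np.ndarray,
    voxel_size_mm: float | np.ndarray,
) -> SmoothnessEstimate:
    """Residual-based smoothness: per-axis FWHM and resel count.

    Residual maps are standardized voxelwise to unit norm across subjects;
    for each axis the mean squared spatial first difference ``lambda``
    estimates ``2 (1 - rho)`` of the spatial autocorrelation, giving
    ``FWHM = sqrt(4 ln 2) * voxel / sqrt(lambda)``. Resels = in-mask voxel
    count times the product over axes of (voxel size / FWHM).
    """
    residuals = np.asarray(residuals, dtype=float)
    if residuals.ndim != 4 or residuals.shape[0] < 3:
        raise ValueError("need >= 3 residual maps, shape (n, x, y, z)")
    mask = np.asarray(mask, dtype=bool)
    voxel = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,)).copy()
    norm = np.sqrt((residuals**2).sum(axis=0))
    ok = mask & (norm > 0)
    u = np.where(ok, residuals / np.where(norm > 0, norm, 1.0), np.nan)
    fwhm = np.full(3, np.nan)
    for ax in range(3):
        if mask.shape[ax] < 2:
            warnings.warn(f"mask thinner than 2 voxels along axis {ax}; excluded")
            continue
        sl_hi = [slice(None)] * 3
        sl_lo = [slice(None)] * 3
        sl_hi[ax] = slice(1, None)
        sl_lo[ax] = slice(None, -1)
        pair_ok = ok[tuple(sl_hi)] & ok[tuple(sl_lo)]
        if not pair_ok.any():
            warnings.warn(f"no valid voxel pairs along axis {ax}; excluded")
            continue
        du = u[(slice(None),) + tuple(sl_hi)] - u[(slice(None),) + tuple(sl_lo)]
        lam = (du[:, pair_ok] ** 2).sum(axis=0).mean()
        fwhm[ax] = math.sqrt(4.0 * math.log(2.0)) * voxel[ax] / math.sqrt(lam)
    if np.isnan(fwhm).all():
        raise ValueError("smoothness could not be estimated along any axis")
    # fall back to the geometric mean of estimated axes for excluded ones
    mean_f = float(np.exp(np.nanmean(np.log(fwhm))))
    filled = np.where(np.isnan(fwhm), mean_f, fwhm)
    resels = float(mask.sum() * np.prod(voxel / filled))
    return SmoothnessEstimate(fwhm_mm=filled, resels=resels)


def _gaussianize(t: np.ndarray, df: int) -> np.ndarray:
    """Probit transform of t tail probabilities (sign-preserving)."""
    p = stats.t.sf(np.abs(t), df)
    z = stats.norm.isf(np.clip(p, 1e-300, 1.0))
    return np.sign(t) * np.clip(z, 0, 38.0)


def _extract_clusters(field: np.ndarray, mask: np.ndarray, threshold: float):
    """Connected suprathreshold clusters (26-connectivity), both signs.

    Yields (sign, boolean component, size) for field*sign >= threshold.
    """
    for sign in (1.0, -1.0):
        supra = mask & (sign * field >= threshold)
        labeled, n_comp = ndimage.label(supra, structure=_CONN26)
        for k in range(1, n_comp + 1):
            comp = labeled == k
            yield sign, comp, int(comp.sum())


def _cluster_row(
    idx: int, comp: np.ndarray, t: np.ndarray, affine: np.ndarray, p_corr: float
) -> dict:
    coords = np.argwhere(comp)
    vals = t[comp]
    # peak |t|; ties broken by lowest linear voxel index (argmax is first max)
    peak = int(np.argmax(np.abs(vals)))
    world = affine @ np.append(coords[peak], 1.0)
    return {
        "label": idx,
        "n_voxels": int(comp.sum()),
        "x_mm": float(world[0]),
        "y_mm": float(world[1]),
        "z_mm": float(world[2]),
        "peak_t": float(vals[peak]),
        "p_corrected": float(p_corr),
    }


def grf_cluster_p(
    cluster_size_vox: int, z_threshold: float, smoothness: SmoothnessEstimate,
    n_mask_voxels: int,
) -> float:
    """GRF corrected p for one cluster of a Gaussian(ized) field.

    Expected cluster count from the 3D Euler-characteristic density at
    threshold u, expected suprathreshold volume from the Gaussian tail,
    and the classical ``exp(-beta k^(2/3))`` extent distribution; the
    family-wise p is ``1 - exp(-E[m] * P(extent >= k))``.
    """
    u = z_threshold
    r = smoothness.resels
    if r <= 0:
        raise ValueError("non-positive resel count")
    ec3 = (4 * math.log(2.0)) ** 1.5 / (2 * math.pi) ** 2 * (u**2 - 1) * math.exp(
        -(u**2) / 2.0
    )
    e_clusters = max(r * ec3, 1e-300)
    e_voxels = n_mask_voxels * stats.norm.sf(u)
    e_extent = max(e_voxels / e_clusters, 1e-300)
    beta = (math.gamma(2.5) / e_extent) ** (2.0 / 3.0)
    p_extent = math.exp(-beta * cluster_size_vox ** (2.0 / 3.0))
    return float(-math.expm1(-e_clusters * p_extent))


def grf_cluster_correct(
    tmap: TStatMap,
    smoothness: SmoothnessEstimate,
    affine: np.ndarray,
    voxel_p: float = 0.005,
    cluster_p: float = 0.01,
    two_tailed: bool = True,
) -> pd.DataFrame:
    """GRF cluster-corrected table of suprathreshold clusters.

    Thresholds |t| at the (two-tailed) ``voxel_p`` quantile of t(df),
    Gaussianizes the threshold, extracts positive and negative clusters
    separately (each tail tested at voxel_p/2 when two-tailed) and keeps
    clusters with corrected p < ``cluster_p``.
    """
    if not (0 < voxel_p < 1 and 0 < cluster_p < 1):
        raise ValueError("probabilities must lie in (0, 1)")
    tail_p = voxel_p / 2.0 if two_tailed else voxel_p
    t_thr = stats.t.isf(tail_p, tmap.df)
    z_thr = stats.norm.isf(tail_p)
    n_mask = int(tmap.mask.sum())
    rows = []
    idx = 1
    for _sign, comp, size in _extract_clusters(tmap.t, tmap.mask, t_thr):
        p_corr = grf_cluster_p(size, z_thr, smoothness, n_mask)
        if p_corr < cluster_p:
            rows.append(_cluster_row(idx, comp, tmap.t, affine, p_corr))
            idx += 1
    return pd.DataFrame(rows, columns=CLUSTER_COLUMNS)


def permutation_cluster_correct(
    maps: np.ndarray,
    design: pd.DataFrame,
    affine: np.ndarray,
    group_col: str = "group",
    covariates: list[str] | None = None,
    mask: np.ndarray | None = None,
    voxel_p: float = 0.005,
    cluster_p: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
    two_tailed: bool = True,
) -> pd.DataFrame:
    """Permutation (Freedman-Lane) cluster correction; oracle for GRF.

    Covariate effects are removed under the reduced model, the reduced
    residuals are row-permuted, refitted under the full model, and the
    null distribution of the maximum cluster extent (over both tails)
    calibrates each observed cluster:
    ``p = (1 + #{null max >= size}) / (1 + n_perm)``.
    """
    maps = np.asarray(maps, dtype=float)
    n = maps.shape[0]
    if mask is None:
        mask = np.ones(maps.shape[1:], dtype=bool)
    tmap, _ = glm_group_t(maps, design, group_col, covariates, mask)
    tail_p = voxel_p / 2.0 if two_tailed else voxel_p
    t_thr = stats.t.isf(tail_p, tmap.df)
    observed = list(_extract_clusters(tmap.t, tmap.mask, t_thr))
    if not observed:
        return pd.DataFrame(columns=CLUSTER_COLUMNS)

    x, _ = _group_design(design, group_col, covariates or [])
    z = np.delete(x, 1, axis=1)  # reduced model: intercept + covariates
    y = maps[:, mask]
    gamma = np.linalg.pinv(z) @ y
    fitted_red = z @ gamma
    resid_red = y - fitted_red

    rng = np.random.default_rng(seed)
    if n <= 10 and math.factorial(n) <= n_perm:
        warnings.warn(
            f"only {math.factorial(n)} distinct permutations for {n} subjects; "
            "using exact enumeration"
        )
        perms = [np.array(p) for p in itertools.permutations(range(n))][1:]
    else:
        perms = [rng.permutation(n) for _ in range(n_perm)]

    pinv_x = np.linalg.pinv(x)
    xtx_inv_11 = np.linalg.inv(x.T @ x)[1, 1]
    df = n - x.shape[1]
    null_max = np.zeros(len(perms), dtype=int)
    for i, perm in enumerate(perms):
        y_star = fitted_red + resid_red[perm]
        beta = pinv_x @ y_star
        resid = y_star - x @ beta
        sigma2 = (resid**2).sum(axis=0) / df
        se = np.sqrt(sigma2 * xtx_inv_11)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_perm = np.where(se > 0, beta[1] / se, 0.0)
        field = np.zeros(maps.shape[1:])
        field[mask] = t_perm
        sizes = [s for _, _, s in _extract_clusters(field, tmap.mask, t_thr)]
        null_max[i] = max(sizes) if sizes else 0

    rows = []
    idx = 1
    for _sign, comp, size in observed:
        p_corr = (1 + int((null_max >= size).sum())) / (1 + len(perms))
        if p_corr < cluster_p:
            rows.append(_cluster_row(idx, comp, tmap.t, affine, p_corr))
            idx += 1
    return pd.DataFrame(rows, columns=CLUSTER_COLUMNS)


def parcel_average(
    map_3d: np.ndarray,
    atlas: Parcellation,
    hemisphere_filter: str = "all",
    mask: np.ndarray | None = None,
) -> pd.Series:
    """Mean of a 3D map within each parcel (optionally left hemisphere only).

    Parcels without in-mask voxels get NaN. Returns a Series indexed by
    region label.
    """
    map_3d = np.asarray(map_3d, dtype=float)
    if map_3d.shape != atlas.labels.shape:
        raise ValueError("map grid does not match atlas grid")
    if hemisphere_filter == "all":
        labels = atlas.region_labels
    elif hemisphere_filter == "left":
        labels = atlas.hemisphere_labels("L")
    else:
        raise ValueError("hemisphere_filter must be 'all' or 'left'")
    if mask is None:
        mask = np.ones(map_3d.shape, dtype=bool)
    out = {}
    for lab in labels:
        sel = (atlas.labels == lab) & mask
        out[lab] = float(map_3d[sel].mean()) if sel.any() else np.nan
    return pd.Series(out, name="value")
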