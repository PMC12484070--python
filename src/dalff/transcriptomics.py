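"""Imaging transcriptomics: expression preprocessing and PLS against a brain map.

The preprocessing primitives mirror the standard microarray-atlas
workflow: intensity-based probe filtering, per-gene probe selection by
correlation with a reference (RNA-seq-like) expression vector, assignment
of tissue samples to atlas parcels within a Euclidean tolerance,
scaled-robust-sigmoid normalization per gene within donor, and a
differential-stability filter (mean inter-donor correlation of regional
profiles).

The modelling stage regresses a regional brain map (here, the
group-difference t profile of windowed-ALFF variability) on the
region x gene expression matrix by univariate-response partial least
squares. Component significance uses spatial spin permutations of parcel
centroids on a sphere (preserving spatial autocorrelation); per-gene
contributions are screened by bootstrap Z = weight / bootstrap SE with
Benjamini-Hochberg FDR over genes.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from ._stats import bh_qvalues, by_qvalues, pearson_r
from .parcellation import Parcellation

__all__ = [
    "DonorSampleTable",
    "PlsResult",
    "SpinNull",
    "filter_probes_by_background",
    "select_probe_per_gene",
    "assign_samples_to_regions",
    "scaled_robust_sigmoid",
    "differential_stability",
    "build_expression_matrix",
    "pls_fit",
    "build_spin_null",
    "spin_p",
    "bootstrap_gene_z",
    "export_gene_lists",
]


@dataclass
class DonorSampleTable:
    """One donor's samples: coordinates, probe expression, annotations.

    ``expression`` and ``above_background`` are probes x samples;
    ``reference`` is genes x samples (an independent expression estimate
    used to pick the best probe per gene); ``probe_gene`` maps each probe
    to exactly one gene symbol.
    """

    donor_id: str
    coords_mm: np.ndarray
    expression: pd.DataFrame
    probe_gene: pd.Series
    above_background: pd.DataFrame
    reference: pd.DataFrame

    def __post_init__(self) -> None:
        self.coords_mm = np.asarray(self.coords_mm, dtype=float)
        if self.coords_mm.shape != (self.expression.shape[1], 3):
            raise ValueError("coords must be (n_samples, 3)")
        if not self.expression.index.equals(self.above_background.index):
            raise ValueError("expression/background probe sets differ")
        if set(self.expression.index) - set(self.probe_gene.index):
            raise ValueError("every probe needs a gene annotation")


# ---------------------------------------------------------------------------
# preprocessing primitives
# ---------------------------------------------------------------------------


def filter_probes_by_background(
    table: DonorSampleTable, min_fraction: float = 0.5
) -> list[str]:
    """Probes whose above-background fraction of samples is >= min_fraction."""
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must lie in (0, 1]")
    if table.expression.shape[1] == 0:
        raise ValueError("empty sample table")
    frac = table.above_background.mean(axis=1)
    return list(frac.index[frac >= min_fraction])


def pooled_background_filter(
    tables: list[DonorSampleTable], min_fraction: float = 0.5
) -> list[str]:
    """Probe filter pooling samples across donors."""
    flags = pd.concat([t.above_background for t in tables], axis=1)
    frac = flags.mean(axis=1)
    return list(frac.index[frac >= min_fraction])


def select_probe_per_gene(
    expression: pd.DataFrame,
    probe_gene: pd.Series,
    reference: pd.DataFrame,
) -> pd.Series:
    """One probe per gene: maximal Pearson correlation with the reference.

    Constant probes are skipped (correlation undefined); genes whose
    probes are all skipped are dropped with a warning. Ties break to the
    first probe in annotation order.
    """
    chosen: dict[str, str] = {}
    for gene, probes in probe_gene.loc[expression.index].groupby(probe_gene):
        best, best_r = None, -np.inf
        ref = reference.loc[gene].to_numpy()
        for probe in probes.index:
            x = expression.loc[probe].to_numpy()
            try:
                r = pearson_r(x, ref)
            except ValueError:
                continue  # zero-variance probe
            if r > best_r:
                best, best_r = probe, r
        if best is None:
            warnings.warn(f"gene {gene!r} dropped: no probe with defined correlation")
            continue
        chosen[gene] = best
    return pd.Series(chosen, name="probe")


def assign_samples_to_regions(
    coords_mm: np.ndarray,
    atlas: Parcellation,
    max_distance_mm: float = 2.0,
) -> np.ndarray:
    """Region label per sample; 0 = unassigned.

    A sample inside a labeled voxel takes that voxel's label; otherwise it
    takes the label of the nearest labeled voxel if that voxel's center is
    within ``max_distance_mm``.
    """
    if max_distance_mm < 0:
        raise ValueError("max_distance_mm must be non-negative")
    coords_mm = np.atleast_2d(np.asarray(coords_mm, dtype=float))
    inv = np.linalg.inv(atlas.affine)
    ijk = (inv @ np.column_stack([coords_mm, np.ones(len(coords_mm))]).T).T[:, :3]
    ijk_round = np.round(ijk).astype(int)
    labels = np.zeros(len(coords_mm), dtype=int)
    shape = np.array(atlas.labels.shape)
    inside = np.all((ijk_round >= 0) & (ijk_round < shape), axis=1)
    for i in np.nonzero(inside)[0]:
        labels[i] = atlas.labels[tuple(ijk_round[i])]
    # nearest labeled voxel for the rest
    need = labels == 0
    if need.any():
        vox = np.argwhere(atlas.labels > 0)
        world = (atlas.affine @ np.column_stack([vox, np.ones(len(vox))]).T).T[:, :3]
        tree = cKDTree(world)
        dist, idx = tree.query(coords_mm[need])
        lab = atlas.labels[tuple(vox[idx].T)]
        labels[need] = np.where(dist <= max_distance_mm, lab, 0)
    return labels


def scaled_robust_sigmoid(values: np.ndarray) -> np.ndarray:
    """Outlier-robust sigmoid normalization to [0, 1].

    ``y = 1 / (1 + exp(-(x - median) / (IQR / 1.35)))`` followed by
    min-max rescaling. The 1.35 factor makes IQR/1.35 a robust SD
    estimate for Gaussian data.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    med = np.median(x)
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        raise ValueError("zero IQR; values are (near-)constant")
    y = 1.0 / (1.0 + np.exp(-(x - med) / (iqr / 1.35)))
    return (y - y.min()) / (y.max() - y.min())


def differential_stability(donor_matrices: dict[str, pd.DataFrame]) -> pd.Series:
    """Per-gene mean inter-donor correlation of regional profiles.

    For every donor pair the Pearson correlation of a gene's profile over
    the regions common to that pair; pairs where the gene is constant in
    either donor are skipped for that gene.
    """
    donors = list(donor_matrices)
    if len(donors) < 2:
        raise ValueError("need at least two donors")
    genes = sorted(set.intersection(*(set(m.columns) for m in donor_matrices.values())))
    sums = pd.Series(0.0, index=genes)
    counts = pd.Series(0, index=genes)
    for i in range(len(donors)):
        for j in range(i + 1, len(donors)):
            a, b = donor_matrices[donors[i]], donor_matrices[donors[j]]
            common = a.index.intersection(b.index)
            if len(common) < 3:
                raise ValueError(
                    f"donors {donors[i]} and {donors[j]} share fewer than 3 regions"
                )
            for g in genes:
                try:
                    r = pearson_r(a.loc[common, g].to_numpy(), b.loc[common, g].to_numpy())
                except ValueError:
                    continue
                sums[g] += r
                counts[g] += 1
    with np.errstate(invalid="ignore"):
        ds = sums / counts.replace(0, np.nan)
    return ds.rename("differential_stability")


def build_expression_matrix(
    tables: list[DonorSampleTable],
    atlas: Parcellation,
    max_distance_mm: float = 2.0,
    min_background_fraction: float = 0.5,
    stability_threshold: float = 0.1,
    hemisphere_filter: str = "left",
) -> pd.DataFrame:
    """Full donor-to-matrix pipeline; returns regions x genes in [0, 1].

    Steps: pooled intensity-based probe filter; per-gene probe selection
    against the pooled reference; sample-to-region assignment; per-donor
    region averaging; scaled-robust-sigmoid per gene within donor;
    differential-stability filter; donor averaging.
    """
    probes = pooled_background_filter(tables, min_background_fraction)
    if not probes:
        raise ValueError("no probe survives the background filter")
    expr_all = pd.concat([t.expression.loc[probes] for t in tables], axis=1)
    expr_all.columns = range(expr_all.shape[1])
    ref_all = pd.concat([t.reference for t in tables], axis=1)
    ref_all.columns = range(ref_all.shape[1])
    gene_probe = select_probe_per_gene(expr_all, tables[0].probe_gene, ref_all)

    if hemisphere_filter == "left":
        keep_regions = atlas.hemisphere_labels("L")
    elif hemisphere_filter == "all":
        keep_regions = atlas.region_labels
    else:
        raise ValueError("hemisphere_filter must be 'left' or 'all'")

    donor_mats: dict[str, pd.DataFrame] = {}
    for t in tables:
        labels = assign_samples_to_regions(t.coords_mm, atlas, max_distance_mm)
        vals = t.expression.loc[gene_probe.to_numpy()]
        vals.index = gene_probe.index
        assigned = pd.DataFrame(vals.T)
        assigned["region"] = labels
        assigned = assigned[assigned["region"].isin(keep_regions)]
        mat = assigned.groupby("region").mean()
        norm = {}
        for g in mat.columns:
            try:
                norm[g] = scaled_robust_sigmoid(mat[g].to_numpy())
            except ValueError:
                warnings.warn(f"gene {g!r} constant in donor {t.donor_id}; dropped")
        donor_mats[t.donor_id] = pd.DataFrame(norm, index=mat.index)

    ds = differential_stability(donor_mats)
    keep_genes = ds.index[ds >= stability_threshold]
    if len(keep_genes) == 0:
        raise ValueError("no gene survives the differential-stability filter")
    stacked = pd.concat(
        [m[keep_genes.intersection(m.columns)] for m in donor_mats.values()]
    )
    out = stacked.groupby(level=0).mean()
    missing = set(keep_regions) - set(out.index)
    if missing:
        raise ValueError(f"regions {sorted(missing)} received no samples")
    return out.loc[sorted(keep_regions)]


# ---------------------------------------------------------------------------
# PLS
# ---------------------------------------------------------------------------


@dataclass
class PlsResult:
    """Univariate-response PLS fit plus optional spin/bootstrap screening.

    ``weights`` are the rotation applied to the standardized gene columns
    (component 1 is proportional to X^T y); ``explained_variance`` is each
    component's share of the response variance; ``component_r`` the
    Pearson r between each score and the response. ``gene_table`` is
    filled by :func:`bootstrap_gene_z`.
    """

    genes: list[str]
    regions: list
    scores: np.ndarray  # regions x components
    weights: np.ndarray  # genes x components (rotation)
    saliences: np.ndarray  # genes x components (unnormalized deflated X'y)
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    explained_variance: np.ndarray
    component_r: np.ndarray
    spin_p: np.ndarray | None = None
    gene_table: pd.DataFrame | None = None


def _standardize_columns(a: np.ndarray) -> np.ndarray:
    mu = a.mean(axis=0)
    sd = a.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant column; cannot standardize")
    return (a - mu) / sd


def pls_fit(
    x: pd.DataFrame,
    y: pd.Series,
    n_components: int = 2,
    standardize: bool = True,
) -> PlsResult:
    """Univariate-response PLS (NIPALS with deflation).

    Successive weight vectors maximize covariance between X-scores and
    the current response residual. X columns and y are z-scored over
    regions first (configurable). Requires X and y over identical region
    sets with no missing entries.
    """
    if not x.index.equals(y.index):
        raise ValueError("X and y must share an identical region index")
    xv = x.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    if np.isnan(xv).any() or np.isnan(yv).any():
        raise ValueError("undefined entries in X or y")
    n, p = xv.shape
    if n < n_components + 2:
        raise ValueError("need at least n_components + 2 regions")
    max_rank = int(np.linalg.matrix_rank(xv - xv.mean(axis=0)))
    if n_components > max_rank:
        warnings.warn(
            f"n_components={n_components} exceeds rank {max_rank}; truncated"
        )
        n_components = max_rank
    if standardize:
        xv = _standardize_columns(xv)
        yv = (yv - yv.mean()) / yv.std(ddof=1)
    xd, yd = xv.copy(), yv.copy()
    w_mat = np.zeros((p, n_components))
    s_mat = np.zeros((p, n_components))
    t_mat = np.zeros((n, n_components))
    p_mat = np.zeros((p, n_components))
    q_vec = np.zeros(n_components)
    for k in range(n_components):
        w = xd.T @ yd
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ValueError("response residual orthogonal to X; too many components")
        s_mat[:, k] = w / (n - 1)  # cross-covariance with the current response
        w = w / nw
        t = xd @ w
        tt = t @ t
        p_load = xd.T @ t / tt
        q = yd @ t / tt
        xd = xd - np.outer(t, p_load)
        yd = yd - q * t
        w_mat[:, k], t_mat[:, k], p_mat[:, k], q_vec[k] = w, t, p_load, q
    # rotation mapping the original X onto scores: T = X W (P'W)^-1
    rotation = w_mat @ np.linalg.inv(p_mat.T @ w_mat)
    ss_y = float(yv @ yv)
    explained = np.array(
        [q_vec[k] ** 2 * (t_mat[:, k] @ t_mat[:, k]) / ss_y for k in range(n_components)]
    )
    comp_r = np.array([pearson_r(t_mat[:, k], yv) for k in range(n_components)])
    return PlsResult(
        genes=list(x.columns),
        regions=list(x.index),
        scores=t_mat,
        weights=rotation,
        saliences=s_mat,
        x_loadings=p_mat,
        y_loadings=q_vec,
        explained_variance=explained,
        component_r=comp_r,
    )


# ---------------------------------------------------------------------------
# spin nulls
# ---------------------------------------------------------------------------


@dataclass
class SpinNull:
    """Precomputed spatial-rotation permutations of region indices."""

    permutations: np.ndarray  # n_spins x n_regions (indices into regions)
    mode: str
    seed: int

    @property
    def n_spins(self) -> int:
        return self.permutations.shape[0]


def build_spin_null(
    sphere_coords: np.ndarray,
    n_spins: int,
    seed: int = 0,
    mode: str = "nearest",
    hemispheres: np.ndarray | None = None,
) -> SpinNull:
    """Spin-permutation null from unit-sphere parcel coordinates.

    Each trial applies one uniformly random 3D rotation; when hemisphere
    flags are given the right hemisphere receives the x-mirrored rotation
    so the two hemispheres spin symmetrically. Each region is then
    reassigned to the nearest rotated centroid (``mode='nearest'``,
    duplicates possible) or by optimal one-to-one matching
    (``mode='permutation'``, a strict permutation).
    """
    coords = np.asarray(sphere_coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 3:
        raise ValueError("need >= 3 unit-sphere coordinates")
    if n_spins < 1:
        raise ValueError("n_spins must be >= 1")
    if mode not in ("nearest", "permutation"):
        raise ValueError("mode must be 'nearest' or 'permutation'")
    n = coords.shape[0]
    if hemispheres is None:
        blocks = [np.arange(n)]
    else:
        hemispheres = np.asarray(hemispheres)
        blocks = [np.nonzero(hemispheres == h)[0] for h in ("L", "R")]
        blocks = [b for b in blocks if b.size]
    mirror = np.diag([-1.0, 1.0, 1.0])
    rng = np.random.default_rng(seed)
    perms = np.zeros((n_spins, n), dtype=int)
    for s in range(n_spins):
        rot = stats.special_ortho_group.rvs(3, random_state=rng)
        for bi, block in enumerate(blocks):
            r = rot if bi == 0 else mirror @ rot @ mirror
            rotated = coords[block] @ r.T
            # distance from each original centroid to each rotated centroid
            d = np.linalg.norm(coords[block][:, None] - rotated[None, :], axis=2)
            if mode == "nearest":
                perms[s, block] = block[np.argmin(d, axis=1)]
            else:
                rows, cols = linear_sum_assignment(d)
                perms[s, block[rows]] = block[cols]
    return SpinNull(permutations=perms, mode=mode, seed=seed)


def spin_p(map_a: np.ndarray, map_b: np.ndarray, null: SpinNull) -> float:
    """Two-tailed spin p for the correlation of two region maps.

    ``p = (1 + #{ |r_null| >= |r_obs| }) / (1 + n_spins)`` where each null
    r correlates the spun map_a against map_b. Never returns 0.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    r_obs = pearson_r(a, b)
    spun = a[null.permutations]  # (n_spins, n_regions)
    spun = spun - spun.mean(axis=1, keepdims=True)
    bc = b - b.mean()
    den = np.linalg.norm(spun, axis=1) * np.linalg.norm(bc)
    with np.errstate(divide="ignore", invalid="ignore"):
        null_r = np.where(den > 0, spun @ bc / np.where(den > 0, den, 1.0), 1.0)
    exceed = int((np.abs(null_r) >= abs(r_obs) - 1e-12).sum())
    return (1 + exceed) / (1 + null.n_spins)


# ---------------------------------------------------------------------------
# bootstrap gene screening
# ---------------------------------------------------------------------------


def bootstrap_gene_z(
    x: pd.DataFrame,
    y: pd.Series,
    component_index: int,
    n_boot: int = 1000,
    seed: int = 0,
    q_threshold: float = 0.05,
    n_components: int | None = None,
    correction: str = "by",
) -> pd.DataFrame:
    """Per-gene bootstrap Z for one PLS component, with BH-FDR screening.

    The per-gene statistic is the component's salience (the unnormalized
    cross-covariance of the gene with the component's response residual);
    unlike the unit-norm weight vector it is free of the O(p/n)
    norm-inflation bias that shrinks naive bootstrap weight replicates.
    Regions are resampled with replacement; each refit component is
    sign-aligned to the original; Z = original salience / bootstrap SE;
    two-tailed p from a t reference with n_regions - 2 df; FDR q over
    genes. Because spatially autocorrelated expression makes the gene
    family strongly dependent (entire blocks of null genes co-align with
    a response realization), the default correction is Benjamini-
    Yekutieli, which controls FDR under arbitrary dependence;
    ``correction='bh'`` selects plain Benjamini-Hochberg. Sign class is
    'PLS+' (q < threshold, Z > 0), 'PLS-' (q < threshold, Z < 0) or 'ns'.
    ``component_index`` is 1-based.
    """
    if n_boot < 100:
        raise ValueError("need n_boot >= 100")
    k = component_index - 1
    n_components = n_components or component_index
    if k < 0 or k >= n_components:
        raise ValueError("component_index must lie in 1..n_components")
    fit = pls_fit(x, y, n_components)
    w0 = fit.saliences[:, k]
    n = len(x)
    rng = np.random.default_rng(seed)
    boots = np.zeros((n_boot, len(w0)))
    got = 0
    while got < n_boot:
        idx = rng.integers(0, n, size=n)
        if len(np.unique(idx)) < n_components + 2:
            continue  # redraw degenerate resamples
        xb = x.iloc[idx].reset_index(drop=True)
        yb = y.iloc[idx].reset_index(drop=True)
        try:
            fb = pls_fit(xb, yb, n_components)
        except ValueError:
            continue
        wb = fb.saliences[:, k]
        sign = 1.0 if wb @ w0 >= 0 else -1.0
        boots[got] = sign * wb
        got += 1
    # error measured about the original estimate: resampling bias inflates
    # the error term instead of being silently discounted
    se = np.sqrt(((boots - w0) ** 2).mean(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, w0 / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(z), n - 2)
    if correction == "by":
        q = by_qvalues(p)
    elif correction == "bh":
        q = bh_qvalues(p)
    else:
        raise ValueError("correction must be 'by' or 'bh'")
    cls = np.where(q < q_threshold, np.where(z > 0, "PLS+", "PLS-"), "ns")
    return pd.DataFrame(
        {"gene": fit.genes, "weight": w0, "z": z, "p": p, "q": q, "class": cls}
    ).set_index("gene")


def export_gene_lists(
    gene_table: pd.DataFrame, z_cut: float, out_dir: str | Path
) -> dict[str, Path]:
    """Write one-symbol-per-line gene lists for enrichment/PPI services.

    Emits the q-screened positive and negative sets and the |Z| > z_cut
    sets. Empty lists produce a file holding only a header comment.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lists = {
        "pls_pos_fdr": gene_table.index[gene_table["class"] == "PLS+"],
        "pls_neg_fdr": gene_table.index[gene_table["class"] == "PLS-"],
        "z_above_cut": gene_table.index[gene_table["z"] > z_cut],
        "z_below_cut": gene_table.index[gene_table["z"] < -z_cut],
    }
    paths = {}
    for name, genes in lists.items():
        path = out_dir / f"{name}.txt"
        with open(path, "w") as fh:
            if len(genes) == 0:
                fh.write("# empty gene list\n")
            else:
                fh.write("\n".join(genes) + "\n")
        paths[name] = path
    return paths


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-symbol-per-line gene list (ignoring comments)."""
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
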