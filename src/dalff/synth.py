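"""Synthetic inputs for every pipeline stage, fully determined by a seed.

The generator emulates a two-group resting-state fMRI study at toy
scale: band-limited BOLD series whose window-to-window oscillation
amplitude fluctuates more strongly in one group within planted atlas
regions (so the CV of windowed ALFF separates the groups there), a
mirrored Voronoi parcellation with world-mm and unit-sphere centroids,
donor-level gene-expression tables with one planted spatial gradient and
spatially autocorrelated noise, and receptor density maps partially
correlated with a target map.

Each voxel's BOLD signal is a single band-interior carrier sinusoid with
a piecewise-constant random amplitude envelope plus white noise; with the
carrier on an exact DFT frequency of the analysis windows the windowed
ALFF is analytically predictable from the envelope, which the cohort
records as ground truth. No attempt is made to model hemodynamic
response functions, physiological noise spectra or scanner artifacts.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .parcellation import Parcellation
from .transcriptomics import DonorSampleTable
from .volume import MotionParams, VolumeSeries

__all__ = [
    "SimulationConfig",
    "SubjectRecord",
    "SyntheticCohort",
    "generate_atlas",
    "generate_bold_cohort",
    "generate_expression",
    "generate_receptor_maps",
]

GROUPS = ("control", "patient")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic two-group BOLD cohort.

    Defaults mirror a typical acquisition where cheap (240 volumes at
    TR 2 s, 0.01-0.1 Hz analysis band, 90 parcels) and shrink the rest
    (12x14x12 grid of 3 mm voxels, 10 subjects per group).
    """

    n_per_group: int = 10
    grid_shape: tuple[int, int, int] = (12, 14, 12)
    voxel_size_mm: float = 3.0
    n_timepoints: int = 240
    tr_seconds: float = 2.0
    band: tuple[float, float] = (0.01, 0.1)
    carrier_hz: float = 0.05
    effect_regions: tuple[int, ...] = (1, 6, 15)
    modulation_depth: dict = field(
        default_factory=lambda: {"control": 0.2, "patient": 0.7}
    )
    modulation_block_tr: int = 10
    noise_sd: float = 0.25
    base_amplitude: float = 1.0
    baseline: float = 100.0
    fraction_high_motion: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        nyquist = 1.0 / (2.0 * self.tr_seconds)
        lo, hi = self.band
        if not (0 < lo < hi <= nyquist):
            raise ValueError(f"band must lie inside (0, {nyquist}] Hz")
        if not (lo <= self.carrier_hz <= hi):
            raise ValueError("carrier frequency must lie inside the band")
        for g, m in self.modulation_depth.items():
            if not (0 <= m <= 1):
                raise ValueError(f"modulation depth for {g!r} outside [0, 1]")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            payload = json.load(fh)
        payload["grid_shape"] = tuple(payload["grid_shape"])
        payload["band"] = tuple(payload["band"])
        payload["effect_regions"] = tuple(payload["effect_regions"])
        return cls(**payload)


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    series: VolumeSeries
    motion: MotionParams
    age: float
    gender: int
    mean_fd_mm: float


@dataclass
class SyntheticCohort:
    """Simulated subjects plus the planted ground truth.

    ``envelopes`` maps subject id to the per-timepoint oscillation
    amplitude of every effect-region voxel (rows follow
    ``effect_voxels``), which makes windowed ALFF predictable exactly.
    """

    subjects: list[SubjectRecord]
    config: SimulationConfig
    effect_voxels: np.ndarray  # (n_eff, 3) voxel indices
    envelopes: dict[str, np.ndarray]  # subject -> (n_eff, T)

    def covariate_table(self) -> pd.DataFrame:
        rows = [
            {
                "subject": s.subject_id,
                "group": 1 if s.group == "patient" else 0,
                "age": s.age,
                "gender": s.gender,
                "mean_fd": s.mean_fd_mm,
            }
            for s in self.subjects
        ]
        return pd.DataFrame(rows).set_index("subject")


def _centered_affine(grid_shape, voxel_size_mm: float) -> np.ndarray:
    affine = np.eye(4)
    affine[:3, :3] = np.eye(3) * voxel_size_mm
    affine[:3, 3] = -(np.asarray(grid_shape, dtype=float) - 1) / 2.0 * voxel_size_mm
    return affine


def generate_atlas(
    n_parcels: int,
    grid_shape: tuple[int, int, int] = (12, 14, 12),
    voxel_size_mm: float = 3.0,
    seed: int = 0,
) -> Parcellation:
    """Mirrored Voronoi parcellation covering the whole grid.

    Seed voxels are drawn in the left half of the x axis and mirrored to
    the right, so parcels come in hemisphere pairs (labels 1..n/2 left,
    n/2+1..n right) and every voxel takes the label of its nearest seed
    in world mm (no ties occur across the mirror plane for integer voxel
    coordinates). Requires an even parcel count and an even x dimension.
    """
    if n_parcels < 2:
        raise ValueError("need at least 2 parcels")
    n_vox = int(np.prod(grid_shape))
    if n_parcels > n_vox:
        raise ValueError("more parcels than voxels")
    if n_parcels % 2 or grid_shape[0] % 2:
        raise ValueError("mirrored atlas needs even n_parcels and even x dimension")
    rng = np.random.default_rng(seed)
    nx, ny, nz = grid_shape
    half = n_parcels // 2
    n_left_vox = (nx // 2) * ny * nz
    if half > n_left_vox:
        raise ValueError("more parcels than voxels in one hemisphere")
    flat = rng.choice(n_left_vox, size=half, replace=False)
    left_seeds = np.column_stack(np.unravel_index(flat, (nx // 2, ny, nz)))
    right_seeds = left_seeds.copy()
    right_seeds[:, 0] = nx - 1 - right_seeds[:, 0]
    seeds = np.vstack([left_seeds, right_seeds]).astype(float)

    affine = _centered_affine(grid_shape, voxel_size_mm)
    grid = np.indices(grid_shape).reshape(3, -1).T.astype(float)
    world = grid * voxel_size_mm + affine[:3, 3]
    seeds_world = seeds * voxel_size_mm + affine[:3, 3]
    d2 = ((world[:, None, :] - seeds_world[None, :, :]) ** 2).sum(axis=2)
    labels = (d2.argmin(axis=1) + 1).reshape(grid_shape)

    rows = []
    for lab in range(1, n_parcels + 1):
        vox = np.argwhere(labels == lab)
        centroid = vox.mean(axis=0) * voxel_size_mm + affine[:3, 3]
        norm = np.linalg.norm(centroid)
        sphere = centroid / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
        seed_mm = seeds_world[lab - 1]
        rows.append(
            {
                "label": lab,
                "hemisphere": "L" if lab <= half else "R",
                "cx_mm": centroid[0],
                "cy_mm": centroid[1],
                "cz_mm": centroid[2],
                "sx": sphere[0],
                "sy": sphere[1],
                "sz": sphere[2],
                "seed_x_mm": seed_mm[0],
                "seed_y_mm": seed_mm[1],
                "seed_z_mm": seed_mm[2],
            }
        )
    regions = pd.DataFrame(rows).set_index("label")
    return Parcellation(labels=labels, affine=affine, regions=regions)


def generate_bold_cohort(config: SimulationConfig, atlas: Parcellation) -> SyntheticCohort:
    """Two groups of amplitude-modulated BOLD series with planted effects.

    Every voxel carries ``baseline + A(t) sin(2 pi f t + phi) + noise``
    where the envelope ``A(t) = A0 (1 + m s(t))`` has blockwise-constant
    random modulation ``s ~ U(-1, 1)``. Inside ``effect_regions`` the
    depth ``m`` is group-specific (patient > control by default); outside
    both groups share the control depth, so group means are identical
    everywhere and only the amplitude variability differs.
    """
    missing = set(config.effect_regions) - set(atlas.region_labels)
    if missing:
        raise ValueError(f"effect regions {sorted(missing)} not in atlas")
    rng = np.random.default_rng(config.seed)
    grid = config.grid_shape
    if tuple(atlas.labels.shape) != tuple(grid):
        raise ValueError("atlas grid does not match config grid")
    t_ax = np.arange(config.n_timepoints) * config.tr_seconds
    n_blocks = -(-config.n_timepoints // config.modulation_block_tr)
    eff_mask = np.isin(atlas.labels, config.effect_regions)
    eff_vox = np.argwhere(eff_mask)
    flat_mask = eff_mask.reshape(-1)
    n_vox = int(np.prod(grid))

    n_total = 2 * config.n_per_group
    n_high = int(round(config.fraction_high_motion * n_total))
    subjects: list[SubjectRecord] = []
    envelopes: dict[str, np.ndarray] = {}
    affine = _centered_affine(grid, config.voxel_size_mm)
    idx = 0
    for group in GROUPS:
        for k in range(config.n_per_group):
            sid = f"{group[:3]}{k:02d}"
            m = np.full(n_vox, config.modulation_depth["control"])
            m[flat_mask] = config.modulation_depth[group]
            s_blocks = rng.uniform(-1.0, 1.0, size=(n_vox, n_blocks))
            s_t = np.repeat(s_blocks, config.modulation_block_tr, axis=1)[
                :, : config.n_timepoints
            ]
            env = config.base_amplitude * (1.0 + m[:, None] * s_t)
            phase = rng.uniform(0, 2 * np.pi, size=n_vox)
            carrier = np.sin(
                2 * np.pi * config.carrier_hz * t_ax[None, :] + phase[:, None]
            )
            noise = rng.normal(0.0, 1.0, size=(n_vox, config.n_timepoints))
            data = config.baseline + env * carrier + config.noise_sd * noise
            series = VolumeSeries(
                data=data.reshape(grid + (config.n_timepoints,)),
                tr=config.tr_seconds,
                affine=affine,
                mask=atlas.mask,
            )
            motion = _motion_table(
                rng, config.n_timepoints, spike=(idx >= n_total - n_high)
            )
            age = float(np.round(rng.normal(55.0, 10.0), 1))
            gender = int(rng.integers(0, 2))
            subjects.append(
                SubjectRecord(
                    subject_id=sid,
                    group=group,
                    series=series,
                    motion=motion,
                    age=age,
                    gender=gender,
                    mean_fd_mm=motion.mean_framewise_displacement(),
                )
            )
            envelopes[sid] = env[flat_mask]
            idx += 1
    return SyntheticCohort(
        subjects=subjects,
        config=config,
        effect_voxels=eff_vox,
        envelopes=envelopes,
    )


def _motion_table(rng: np.random.Generator, t: int, spike: bool) -> MotionParams:
    steps = rng.normal(0.0, 0.03, size=(t, 6))
    walk = np.clip(np.cumsum(steps, axis=0), -1.2, 1.2)
    if spike:
        frame = int(rng.integers(t // 4, 3 * t // 4))
        walk[frame:, 0] += 2.6  # exceeds a 2 mm exclusion threshold
    return MotionParams(walk)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def _spatial_smoother(centroids_mm: np.ndarray, length_mm: float) -> np.ndarray:
    """Row-normalized Gaussian smoothing kernel over region centroids."""
    d2 = ((centroids_mm[:, None, :] - centroids_mm[None, :, :]) ** 2).sum(axis=2)
    k = np.exp(-d2 / (2.0 * length_mm**2))
    return k / np.linalg.norm(k, axis=1, keepdims=True)


def generate_expression(
    n_genes: int,
    n_donors: int,
    target_map: pd.Series,
    centroids_mm: np.ndarray,
    planted_fraction: float = 0.1,
    autocorr_length_mm: float = 6.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    n_probes_per_gene: int = 2,
    bad_probe_fraction: float = 0.15,
) -> tuple[list[DonorSampleTable], pd.DataFrame, pd.DataFrame]:
    """Donor sample tables plus the ground-truth regions x genes matrix.

    A ``planted_fraction`` of genes follows ``sign * z(target_map) +
    noise_sd * eta`` with spatially autocorrelated noise ``eta`` (white
    noise smoothed over centroids at scale ``autocorr_length_mm``); half
    the planted genes load positively, half negatively; the rest are pure
    autocorrelated noise. Donor tables add donor-specific affine scaling,
    probe noise, above-background flags and a per-gene reference vector so
    probe filtering and selection are exercisable.

    Returns ``(donor_tables, expression_matrix, truth)`` where ``truth``
    holds per-gene ``planted`` and ``sign`` columns.
    """
    if not (0 <= planted_fraction <= 1):
        raise ValueError("planted_fraction must lie in [0, 1]")
    regions = target_map.index
    n_regions = len(regions)
    centroids_mm = np.asarray(centroids_mm, dtype=float)
    if centroids_mm.shape != (n_regions, 3):
        raise ValueError("centroids must be (n_regions, 3)")
    n_planted = int(round(planted_fraction * n_genes))
    if 0 < planted_fraction and n_planted < 2:
        warnings.warn("fewer than 2 planted genes; degenerate signal")
    rng = np.random.default_rng(seed)
    z_t = target_map.to_numpy(dtype=float)
    z_t = (z_t - z_t.mean()) / z_t.std(ddof=1)
    smoother = _spatial_smoother(centroids_mm, autocorr_length_mm)

    genes = [f"G{i:04d}" for i in range(n_genes)]
    profiles = np.zeros((n_regions, n_genes))
    signs = np.zeros(n_genes, dtype=int)
    for j in range(n_genes):
        eta = smoother @ rng.normal(0.0, 1.0, size=n_regions)
        if j < n_planted:
            signs[j] = 1 if j < (n_planted + 1) // 2 else -1
            profiles[:, j] = signs[j] * z_t + noise_sd * eta
        else:
            profiles[:, j] = eta
    expr_matrix = pd.DataFrame(profiles, index=regions, columns=genes)
    truth = pd.DataFrame(
        {"planted": signs != 0, "sign": signs}, index=pd.Index(genes, name="gene")
    )

    probe_ids = [f"{g}_p{k}" for g in genes for k in range(n_probes_per_gene)]
    probe_gene = pd.Series(
        [g for g in genes for _ in range(n_probes_per_gene)],
        index=probe_ids,
        name="gene",
    )
    bad_genes = set(
        rng.choice(genes, size=int(round(bad_probe_fraction * n_genes)), replace=False)
    )

    tables: list[DonorSampleTable] = []
    for d in range(n_donors):
        extra = rng.choice(n_regions, size=max(1, n_regions // 5), replace=False)
        region_idx = np.concatenate([np.arange(n_regions), extra])
        coords = centroids_mm[region_idx] + rng.normal(0.0, 0.4, size=(len(region_idx), 3))
        base = profiles[region_idx]  # (n_samples, n_genes)
        scale = rng.uniform(0.8, 1.2, size=n_genes)
        shift = rng.normal(0.0, 0.3, size=n_genes)
        donor_vals = base * scale[None, :] + shift[None, :]
        n_samples = len(region_idx)
        expr_rows, bg_rows = [], []
        for g_i, g in enumerate(genes):
            for k in range(n_probes_per_gene):
                probe_noise = 0.05 if k == 0 else 0.5
                expr_rows.append(
                    donor_vals[:, g_i] + rng.normal(0.0, probe_noise, size=n_samples)
                )
                rate = 0.3 if (k == 1 and g in bad_genes) else 0.95
                bg_rows.append(rng.random(n_samples) < rate)
        expression = pd.DataFrame(expr_rows, index=probe_ids)
        background = pd.DataFrame(bg_rows, index=probe_ids)
        reference = pd.DataFrame(
            donor_vals.T + rng.normal(0.0, 0.02, size=(n_genes, n_samples)),
            index=genes,
        )
        tables.append(
            DonorSampleTable(
                donor_id=f"donor{d}",
                coords_mm=coords,
                expression=expression,
                probe_gene=probe_gene,
                above_background=background,
                reference=reference,
            )
        )
    return tables, expr_matrix, truth


def generate_receptor_maps(
    n_maps: int,
    target_map: pd.Series,
    correlated_indices: tuple[int, ...] = (),
    rho: float = 0.6,
    seed: int = 0,
) -> pd.DataFrame:
    """Regions x receptors density panel, strictly positive.

    Maps at ``correlated_indices`` have population correlation ``rho``
    with the target map; the rest are independent Gaussian noise. Each
    map is affinely shifted to be strictly positive (densities), which
    leaves every Pearson correlation unchanged.
    """
    if abs(rho) > 1:
        raise ValueError("|rho| must be <= 1")
    rng = np.random.default_rng(seed)
    z_t = target_map.to_numpy(dtype=float)
    z_t = (z_t - z_t.mean()) / z_t.std(ddof=1)
    n = len(z_t)
    cols = {}
    for i in range(n_maps):
        e = rng.normal(0.0, 1.0, size=n)
        if i in correlated_indices:
            m = rho * z_t + np.sqrt(1.0 - rho**2) * e
        else:
            m = e
        cols[f"rec{i:02d}"] = m - m.min() + 0.5
    return pd.DataFrame(cols, index=target_map.index)
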