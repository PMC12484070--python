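"""End-to-end orchestration: simulate -> preprocess -> dALFF -> group stats
-> PLS transcriptomics -> receptor association -> report.

Every stage reads its inputs and writes its outputs under a single run
directory, with a JSON provenance record (settings, seed, input hashes)
per stage, so the pipeline can be restarted at any stage and rerun
bit-identically from the same configuration.

Stage order for preprocessing is discard -> motion QC -> spatial
smoothing -> nuisance regression; temporal band restriction is not a
separate filtering step because the ALFF definition already embeds the
band. The transcriptomics and receptor stages consume the group t-map of
the configured analysis window (50 TR by default).
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import core, inference, preprocess, receptors, synth, transcriptomics
from .parcellation import Parcellation
from .volume import MotionParams, VolumeSeries

__all__ = ["PipelineConfig", "run_pipeline", "render_report", "STAGES"]

log = logging.getLogger("dalff.pipeline")


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; serializable to/from JSON."""

    simulation: synth.SimulationConfig = field(default_factory=synth.SimulationConfig)
    n_discard: int = 10
    window_lengths_tr: tuple[int, ...] = (30, 50, 80)
    window_step_tr: int = 2
    standardize: str = "zscore"
    smooth_fwhm_mm: float = 6.0
    trans_limit_mm: float = 2.0
    rot_limit_deg: float = 2.0
    covariates: tuple[str, ...] = ("age", "gender", "mean_fd")
    voxel_p: float = 0.005
    cluster_p: float = 0.01
    analysis_window_tr: int = 50
    n_parcels: int = 90
    n_genes: int = 120
    n_donors: int = 3
    planted_fraction: float = 0.1
    expression_noise_sd: float = 0.5
    autocorr_length_mm: float = 6.0
    pls_component: int = 1
    pls_n_components: int = 2
    n_spins: int = 1000
    n_boot: int = 1000
    q_threshold: float = 0.05
    z_cut: float = 3.0
    n_receptor_maps: int = 20
    receptor_correlated: tuple[int, ...] = (0, 1)
    receptor_rho: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        for p, name in [(self.voxel_p, "voxel_p"), (self.cluster_p, "cluster_p"),
                        (self.q_threshold, "q_threshold")]:
            if not (0 < p < 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.analysis_window_tr not in self.window_lengths_tr:
            raise ValueError("analysis_window_tr must be one of window_lengths_tr")

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = json.load(fh)
        sim = payload.pop("simulation", {})
        sim["grid_shape"] = tuple(sim.get("grid_shape", (12, 14, 12)))
        sim["band"] = tuple(sim.get("band", (0.01, 0.1)))
        sim["effect_regions"] = tuple(sim.get("effect_regions", (1, 6, 15)))
        for key in ("window_lengths_tr", "covariates", "receptor_correlated"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(simulation=synth.SimulationConfig(**sim), **payload)


def _sha(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def _provenance(run_dir: Path, stage: str, settings: dict, inputs: list[Path]) -> None:
    rec = {
        "stage": stage,
        "settings": settings,
        "inputs": {str(p.relative_to(run_dir)): _sha(p) for p in inputs if p.exists()},
    }
    with open(run_dir / f"provenance_{stage}.json", "w") as fh:
        json.dump(rec, fh, indent=2, default=str)


def _load_atlas(run_dir: Path) -> Parcellation:
    return Parcellation.load(run_dir / "atlas.nii", run_dir / "regions.tsv")


def _target_maps(atlas: Parcellation, effect_regions) -> pd.Series:
    """Ground-truth group-difference profile: effect-region indicator."""
    ind = pd.Series(0.0, index=atlas.regions.index)
    ind.loc[list(effect_regions)] = 1.0
    return ind


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: PipelineConfig, run_dir: Path) -> None:
    run_dir.mkdir(parents=True, exist_ok=True)
    sim = cfg.simulation
    atlas = synth.generate_atlas(
        cfg.n_parcels, sim.grid_shape, sim.voxel_size_mm, seed=sim.seed
    )
    atlas.save(run_dir / "atlas.nii", run_dir / "regions.tsv")
    cohort = synth.generate_bold_cohort(sim, atlas)
    (run_dir / "bold").mkdir(exist_ok=True)
    (run_dir / "motion").mkdir(exist_ok=True)
    for s in cohort.subjects:
        s.series.save(run_dir / "bold" / f"{s.subject_id}.nii")
        s.motion.save(run_dir / "motion" / f"{s.subject_id}.txt")
    cohort.covariate_table().to_csv(run_dir / "covariates.tsv", sep="\t")

    # expression: planted against the left-hemisphere effect indicator
    left = atlas.hemisphere_labels("L")
    target = _target_maps(atlas, sim.effect_regions).loc[left]
    centroids = atlas.regions.loc[left, ["cx_mm", "cy_mm", "cz_mm"]].to_numpy()
    tables, expr_truth, gene_truth = synth.generate_expression(
        n_genes=cfg.n_genes,
        n_donors=cfg.n_donors,
        target_map=target,
        centroids_mm=centroids,
        planted_fraction=cfg.planted_fraction,
        autocorr_length_mm=cfg.autocorr_length_mm,
        noise_sd=cfg.expression_noise_sd,
        seed=sim.seed + 1,
    )
    donors_dir = run_dir / "donors"
    for t in tables:
        d = donors_dir / t.donor_id
        d.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(t.coords_mm, columns=["x_mm", "y_mm", "z_mm"]).to_csv(
            d / "samples.tsv", sep="\t", index_label="sample"
        )
        t.expression.to_csv(d / "expression.tsv", sep="\t", index_label="probe")
        t.probe_gene.rename("gene").to_csv(d / "probes.tsv", sep="\t", index_label="probe")
        t.above_background.astype(int).to_csv(
            d / "background.tsv", sep="\t", index_label="probe"
        )
        t.reference.to_csv(d / "reference.tsv", sep="\t", index_label="gene")
    expr_truth.to_csv(run_dir / "expression_truth.tsv", sep="\t", index_label="region")
    gene_truth.to_csv(run_dir / "gene_truth.tsv", sep="\t")

    target_all = _target_maps(atlas, sim.effect_regions)
    panel = synth.generate_receptor_maps(
        cfg.n_receptor_maps,
        target_all,
        correlated_indices=cfg.receptor_correlated,
        rho=cfg.receptor_rho,
        seed=sim.seed + 2,
    )
    panel.to_csv(run_dir / "receptors.tsv", sep="\t", index_label="region")
    sim.to_json(run_dir / "sim_config.json")
    _provenance(run_dir, "simulate", asdict(sim), [])


def stage_preprocess(cfg: PipelineConfig, run_dir: Path) -> None:
    atlas = _load_atlas(run_dir)
    cov = pd.read_csv(run_dir / "covariates.tsv", sep="\t").set_index("subject")
    prep_dir = run_dir / "prep"
    prep_dir.mkdir(exist_ok=True)
    qc_rows = []
    retained = []
    for sid in cov.index:
        series = VolumeSeries.from_nifti(
            run_dir / "bold" / f"{sid}.nii", mask=atlas.mask
        )
        motion = MotionParams.load(run_dir / "motion" / f"{sid}.txt")
        series, motion = preprocess.discard_initial(series, cfg.n_discard, motion)
        qc = preprocess.motion_qc(motion, cfg.trans_limit_mm, cfg.rot_limit_deg)
        qc_rows.append(
            {
                "subject": sid,
                "max_trans_x": qc.max_translation_mm[0],
                "max_trans_y": qc.max_translation_mm[1],
                "max_trans_z": qc.max_translation_mm[2],
                "max_rot_pitch": qc.max_rotation_deg[0],
                "max_rot_roll": qc.max_rotation_deg[1],
                "max_rot_yaw": qc.max_rotation_deg[2],
                "verdict": "pass" if qc.passed else "fail",
            }
        )
        if not qc.passed:
            log.info("subject %s excluded by motion QC", sid)
            continue
        series = preprocess.gaussian_smooth(series, cfg.smooth_fwhm_mm)
        series = preprocess.nuisance_regress(
            series,
            regressors=preprocess.friston24(motion),
            add_linear_trend=True,
            add_global_signal=True,
        )
        series.save(prep_dir / f"{sid}.nii")
        retained.append(sid)
    pd.DataFrame(qc_rows).to_csv(run_dir / "qc_report.tsv", sep="\t", index=False)
    cov.loc[retained].to_csv(run_dir / "covariates_retained.tsv", sep="\t")
    _provenance(
        run_dir,
        "preprocess",
        {
            "n_discard": cfg.n_discard,
            "smooth_fwhm_mm": cfg.smooth_fwhm_mm,
            "trans_limit_mm": cfg.trans_limit_mm,
            "rot_limit_deg": cfg.rot_limit_deg,
        },
        [run_dir / "covariates.tsv"],
    )


def stage_dalff(cfg: PipelineConfig, run_dir: Path) -> None:
    atlas = _load_atlas(run_dir)
    cov = pd.read_csv(run_dir / "covariates_retained.tsv", sep="\t").set_index("subject")
    band = core.BandSpec(*cfg.simulation.band)
    out_dir = run_dir / "dalff"
    out_dir.mkdir(exist_ok=True)
    for length in cfg.window_lengths_tr:
        window = core.WindowSpec(length_tr=length, step_tr=cfg.window_step_tr)
        stack = []
        n_win = None
        for sid in cov.index:
            series = VolumeSeries.from_nifti(
                run_dir / "prep" / f"{sid}.nii", mask=atlas.mask
            )
            alff_stack = core.sliding_window_alff(series, window, band)
            maps = core.dalff_cv(alff_stack, window, band, mask=atlas.mask)
            if cfg.standardize != "none":
                maps = core.standardize_dalff(maps, cfg.standardize)
            stack.append(maps.cv_map)
            n_win = maps.n_windows
        arr = np.stack(stack, axis=-1).astype(np.float32)
        nib.save(
            nib.Nifti1Image(arr, atlas.affine), out_dir / f"cv_w{length:03d}.nii"
        )
        with open(out_dir / f"cv_w{length:03d}.json", "w") as fh:
            json.dump(
                {
                    "window_length_tr": length,
                    "step_tr": cfg.window_step_tr,
                    "band": list(cfg.simulation.band),
                    "n_windows": n_win,
                    "standardize": cfg.standardize,
                    "subjects": list(cov.index),
                },
                fh,
                indent=2,
            )
    _provenance(
        run_dir,
        "dalff",
        {"windows": list(cfg.window_lengths_tr), "step": cfg.window_step_tr},
        [run_dir / "covariates_retained.tsv"],
    )


def stage_group(cfg: PipelineConfig, run_dir: Path) -> None:
    atlas = _load_atlas(run_dir)
    cov = pd.read_csv(run_dir / "covariates_retained.tsv", sep="\t").set_index("subject")
    group_dir = run_dir / "group"
    group_dir.mkdir(exist_ok=True)
    voxel = np.linalg.norm(atlas.affine[:3, :3], axis=0)
    for length in cfg.window_lengths_tr:
        img = nib.load(run_dir / "dalff" / f"cv_w{length:03d}.nii")
        maps = np.moveaxis(np.asarray(img.get_fdata(), dtype=float), -1, 0)
        tmap, resid = inference.glm_group_t(
            maps, cov, group_col="group", covariates=list(cfg.covariates),
            mask=atlas.mask,
        )
        smooth = inference.estimate_smoothness(resid, tmap.mask, voxel)
        clusters = inference.grf_cluster_correct(
            tmap, smooth, atlas.affine, cfg.voxel_p, cfg.cluster_p
        )
        nib.save(
            nib.Nifti1Image(tmap.t.astype(np.float32), atlas.affine),
            group_dir / f"tmap_w{length:03d}.nii",
        )
        clusters.to_csv(
            group_dir / f"clusters_w{length:03d}.tsv", sep="\t", index=False
        )
    # demographics-style table on the retained cohort
    rows = []
    g1 = cov[cov["group"] == 1]
    g0 = cov[cov["group"] == 0]
    for name in ("age", "mean_fd"):
        t, df = inference.summary_two_sample_t(
            g1[name].mean(), g1[name].std(ddof=1), len(g1),
            g0[name].mean(), g0[name].std(ddof=1), len(g0),
        )
        rows.append({"variable": name, "statistic": t, "df": df, "test": "pooled_t"})
    counts = pd.crosstab(cov["group"], cov["gender"])
    if counts.shape == (2, 2):
        chi2, df = inference.chi_square_2x2(
            counts.iloc[1, 0], counts.iloc[1, 1], counts.iloc[0, 0], counts.iloc[0, 1]
        )
        rows.append({"variable": "gender", "statistic": chi2, "df": df, "test": "chi2"})
    pd.DataFrame(rows).to_csv(run_dir / "demographics.tsv", sep="\t", index=False)
    _provenance(
        run_dir,
        "group",
        {"voxel_p": cfg.voxel_p, "cluster_p": cfg.cluster_p,
         "covariates": list(cfg.covariates)},
        [run_dir / "covariates_retained.tsv"],
    )


def _read_donors(run_dir: Path) -> list[transcriptomics.DonorSampleTable]:
    tables = []
    for d in sorted((run_dir / "donors").iterdir()):
        coords = pd.read_csv(d / "samples.tsv", sep="\t", index_col="sample")
        expr = pd.read_csv(d / "expression.tsv", sep="\t", index_col="probe")
        probes = pd.read_csv(d / "probes.tsv", sep="\t", index_col="probe")["gene"]
        bg = pd.read_csv(d / "background.tsv", sep="\t", index_col="probe").astype(bool)
        ref = pd.read_csv(d / "reference.tsv", sep="\t", index_col="gene")
        tables.append(
            transcriptomics.DonorSampleTable(
                donor_id=d.name,
                coords_mm=coords.to_numpy(),
                expression=expr,
                probe_gene=probes,
                above_background=bg,
                reference=ref,
            )
        )
    return tables


def stage_pls(cfg: PipelineConfig, run_dir: Path) -> None:
    atlas = _load_atlas(run_dir)
    length = cfg.analysis_window_tr
    img = nib.load(run_dir / "group" / f"tmap_w{length:03d}.nii")
    tmap = np.asarray(img.get_fdata(), dtype=float)
    tvec_left = inference.parcel_average(tmap, atlas, hemisphere_filter="left")

    tables = _read_donors(run_dir)
    expr = transcriptomics.build_expression_matrix(
        tables, atlas, hemisphere_filter="left"
    )
    common = expr.index.intersection(tvec_left.dropna().index)
    expr = expr.loc[common]
    y = tvec_left.loc[common]

    fit = transcriptomics.pls_fit(expr, y, n_components=cfg.pls_n_components)
    left = atlas.regions.loc[common]
    null = transcriptomics.build_spin_null(
        left[["sx", "sy", "sz"]].to_numpy(),
        n_spins=cfg.n_spins,
        seed=cfg.seed + 10,
        hemispheres=left["hemisphere"].to_numpy(),
    )
    spins = np.array(
        [
            transcriptomics.spin_p(fit.scores[:, k], y.to_numpy(), null)
            for k in range(fit.scores.shape[1])
        ]
    )
    fit.spin_p = spins
    gene_table = transcriptomics.bootstrap_gene_z(
        expr,
        y,
        component_index=cfg.pls_component,
        n_boot=cfg.n_boot,
        seed=cfg.seed + 11,
        q_threshold=cfg.q_threshold,
        n_components=cfg.pls_n_components,
    )
    pls_dir = run_dir / "pls"
    pls_dir.mkdir(exist_ok=True)
    gene_table.to_csv(pls_dir / "gene_table.tsv", sep="\t")
    transcriptomics.export_gene_lists(gene_table, cfg.z_cut, pls_dir / "gene_lists")
    summary = {
        "analysis_window_tr": length,
        "n_regions": len(common),
        "n_genes": expr.shape[1],
        "component": cfg.pls_component,
        "explained_variance": fit.explained_variance.tolist(),
        "component_r": fit.component_r.tolist(),
        "spin_p": spins.tolist(),
        "n_spins": cfg.n_spins,
        "n_boot": cfg.n_boot,
        "q_threshold": cfg.q_threshold,
        "n_pls_pos": int((gene_table["class"] == "PLS+").sum()),
        "n_pls_neg": int((gene_table["class"] == "PLS-").sum()),
        "seed": cfg.seed,
    }
    with open(pls_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    _provenance(run_dir, "pls", {"component": cfg.pls_component,
                                 "n_spins": cfg.n_spins, "n_boot": cfg.n_boot},
                [run_dir / "group" / f"tmap_w{length:03d}.nii"])


def stage_receptors(cfg: PipelineConfig, run_dir: Path) -> None:
    atlas = _load_atlas(run_dir)
    length = cfg.analysis_window_tr
    img = nib.load(run_dir / "group" / f"tmap_w{length:03d}.nii")
    tmap = np.asarray(img.get_fdata(), dtype=float)
    tvec = inference.parcel_average(tmap, atlas, hemisphere_filter="all").dropna()
    panel = pd.read_csv(run_dir / "receptors.tsv", sep="\t", index_col="region")
    panel = panel.loc[tvec.index]
    regions = atlas.regions.loc[tvec.index]
    null = transcriptomics.build_spin_null(
        regions[["sx", "sy", "sz"]].to_numpy(),
        n_spins=cfg.n_spins,
        seed=cfg.seed + 20,
        hemispheres=regions["hemisphere"].to_numpy(),
    )
    table = receptors.correlate_panel(tvec, panel, null, cfg.q_threshold)
    table.to_csv(run_dir / "receptor_assoc.tsv", sep="\t")
    _provenance(run_dir, "receptors", {"n_spins": cfg.n_spins,
                                       "fdr_threshold": cfg.q_threshold},
                [run_dir / "receptors.tsv"])


def render_report(run_dir: str | Path) -> Path:
    """Assemble a human-readable markdown summary from stage artifacts."""
    run_dir = Path(run_dir)
    lines = ["# Dynamic ALFF pipeline report", ""]

    demo = run_dir / "demographics.tsv"
    lines.append("## Cohort statistics")
    if demo.exists():
        lines.append(pd.read_csv(demo, sep="\t").to_string(index=False))
    else:
        lines.append("*missing: demographics*")
    lines.append("")

    lines.append("## Cluster tables")
    found = False
    for path in sorted(run_dir.glob("group/clusters_w*.tsv")):
        found = True
        tab = pd.read_csv(path, sep="\t")
        lines.append(f"### {path.stem}")
        if len(tab):
            lines.append(tab.to_string(index=False))
        else:
            lines.append("no suprathreshold clusters")
        lines.append("")
    if not found:
        lines.append("*missing: cluster tables*")
        lines.append("")

    lines.append("## PLS transcriptomics")
    summ = run_dir / "pls" / "summary.json"
    if summ.exists():
        with open(summ) as fh:
            s = json.load(fh)
        k = s["component"] - 1
        lines.append(
            f"component {s['component']}: explained variance "
            f"{100 * s['explained_variance'][k]:.2f}%, "
            f"r = {s['component_r'][k]:.4f}, spin p = {s['spin_p'][k]:.4f}"
        )
        lines.append(
            f"significant genes: {s['n_pls_pos']} positive, {s['n_pls_neg']} negative "
            f"(q < {s['q_threshold']})"
        )
    else:
        lines.append("*missing: PLS summary*")
    lines.append("")

    lines.append("## Receptor/transporter association")
    rec = run_dir / "receptor_assoc.tsv"
    if rec.exists():
        tab = pd.read_csv(rec, sep="\t")
        lines.append(tab.to_string(index=False))
    else:
        lines.append("*missing: receptor table*")
    lines.append("")

    out = run_dir / "report.md"
    out.write_text("\n".join(lines))
    return out


STAGES = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "dalff": stage_dalff,
    "group": stage_group,
    "pls": stage_pls,
    "receptors": stage_receptors,
}


def run_pipeline(cfg: PipelineConfig, run_dir: str | Path,
                 stages: list[str] | None = None) -> Path:
    """Execute the pipeline (or a subset of stages) into ``run_dir``."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg.to_json(run_dir / "pipeline_config.json")
    for name in stages or list(STAGES):
        fn = STAGES[name]
        t0 = time.time()
        log.info("stage %s started", name)
        try:
            fn(cfg, run_dir)
        except Exception as exc:  # noqa: BLE001 - annotate the failing stage
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        log.info("stage %s finished in %.1fs", name, time.time() - t0)
    if stages is None or "receptors" in stages:
        render_report(run_dir)
    return run_dir
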