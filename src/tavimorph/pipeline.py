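"""End-to-end orchestration: simulate -> atlas -> statistics -> report.

Runs the full analysis on a synthetic cohort with fixed seeds and writes
per-stage outputs plus a single JSON report.  Stages write their outputs
under ``<out>/<stage>/`` and a checkpoint JSON; a rerun with
``resume=True`` reloads finished stages instead of recomputing them, so
a failed run restarts where it stopped.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calcium_model as cm
from . import clinical_stats as cs
from . import io as tio
from . import shape_stats as ss
from .atlas import AtlasConfig, AtlasModel, estimate_atlas, pca_modes
from .deformation import DeformationKernel, MomentaField
from .synthetic import GeneratorConfig, sample_cohort

log = logging.getLogger("tavimorph")

DEFAULT_STAGES = ("simulate", "atlas", "shape_stats", "calcium",
                  "clinical", "report")


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run (field-standard defaults)."""

    n: int = 30
    seed: int = 7
    lambda_v: float = 11.0
    lambda_w: float = 7.0
    noise: float = 2.0
    theta: float = 2.2
    permutations: int = 200
    atlas_subjects: int = 12        # subset fitted by the atlas stage
    n_native: int = 3               # subjects run through native round-trip
    mesh_rings: int = 16
    mesh_azimuth: int = 14
    stages: tuple = DEFAULT_STAGES
    resume: bool = False
    atlas_dir: str | None = None    # precomputed momenta: skip the fit

    def generator(self) -> GeneratorConfig:
        return GeneratorConfig(n=self.n, lambda_v=self.lambda_v,
                               theta=self.theta, n_rings=self.mesh_rings,
                               n_azimuth=self.mesh_azimuth)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def _write_json(path: Path, obj) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, default=_json_default))


def run(config: PipelineConfig, out_dir,
        write_meshes: bool = True) -> dict:
    """Execute the pipeline; returns (and writes) the report dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(config)}
    t0 = time.time()

    def stage_enabled(name):
        return name in config.stages

    def checkpoint(name):
        return out / f"{name}.json"

    # -- simulate -------------------------------------------------------
    log.info("stage=simulate n=%d seed=%d", config.n, config.seed)
    cohort = sample_cohort(config.generator(), seed=config.seed)
    sim_dir = out / "simulate"
    sim_dir.mkdir(exist_ok=True)
    cohort.covariates.to_csv(sim_dir / "covariates.csv", index=False)
    if write_meshes:
        tio.write_mesh(cohort.ground_truth.template, sim_dir / "template.ply")
        for mesh in cohort.meshes:
            tio.write_mesh(mesh, sim_dir / "meshes" / f"{mesh.name}.ply")
    report["simulate"] = {
        "n": config.n, "seed": config.seed,
        "annulus_mean_mm": float(cohort.covariates["annulus_mm"].mean()),
        "annulus_sd_mm": float(cohort.covariates["annulus_mm"].std()),
        "calcium_mean_mm3": float(
            cohort.covariates["calcium_volume_mm3"].mean()),
    }
    _write_json(checkpoint("simulate"), report["simulate"])

    # -- atlas ----------------------------------------------------------
    atlas = None
    if stage_enabled("atlas"):
        n_fit = min(config.atlas_subjects, config.n)
        if config.atlas_dir:
            log.info("stage=atlas precomputed dir=%s", config.atlas_dir)
            atlas = _load_atlas(config.atlas_dir, config, cohort)
            report["atlas"] = {"precomputed": True,
                               "n_subjects": atlas.n_subjects}
        else:
            log.info("stage=atlas n_fit=%d lambda_v=%.1f lambda_w=%.1f",
                     n_fit, config.lambda_v, config.lambda_w)
            cfg = AtlasConfig(lambda_v=config.lambda_v,
                              lambda_w=config.lambda_w, noise=config.noise,
                              max_rounds=2, max_iter=120)
            atlas, fit_report = estimate_atlas(cohort.meshes[:n_fit], cfg)
            report["atlas"] = fit_report.summary()
            report["atlas"]["n_subjects"] = n_fit
            atlas_dir = out / "atlas"
            tio.write_mesh(atlas.template, atlas_dir / "template.ply")
            for sid, mom in zip(atlas.subject_ids, atlas.momenta):
                tio.write_momenta(mom, atlas.grid,
                                  atlas_dir / f"momenta_{sid}.csv",
                                  meta={"lambda_v": config.lambda_v,
                                        "lambda_w": config.lambda_w})
            modes = pca_modes(atlas, n_modes=3)
            report["atlas"]["mode_variance_fraction"] = \
                modes["variance_fraction"][:3]
        _write_json(checkpoint("atlas"), report["atlas"])

    # -- shape statistics (on the generator momenta: full cohort) -------
    if stage_enabled("shape_stats"):
        log.info("stage=shape_stats B=%d", config.permutations)
        gt = cohort.ground_truth
        cov = cohort.covariates
        momenta = cohort.momenta
        rng_seed = config.seed + 1
        sex = (cov["sex"] == "male").astype(int).to_numpy()
        res_sex = ss.max_stat_permutation_test(
            momenta, sex, statistic="hotelling", B=config.permutations,
            seed=rng_seed)
        res_ann = ss.max_stat_permutation_test(
            momenta, cov["annulus_mm"].to_numpy(), statistic="lr",
            B=config.permutations, seed=rng_seed + 1)
        adj = ss.adjusted_test(momenta, sex,
                               cov[["annulus_mm"]], statistic="hotelling",
                               B=config.permutations, seed=rng_seed + 2)
        report["shape_stats"] = {
            "sex": {"p": res_sex.p_value, "r2_pct": res_sex.r2,
                    "max_t2": res_sex.max_stat},
            "annulus": {"p": res_ann.p_value, "r2_pct": res_ann.r2},
            "sex_adjusted_annulus": {"p": adj.p_value, "r2_pct": adj.r2},
            "B": config.permutations,
        }
        gt_atlas = _gt_atlas(cohort, config)
        vertex_map = ss.momenta_stat_maps_export(res_sex, gt_atlas)
        tio.write_mesh(gt_atlas.template, out / "shape_stats"
                       / "sex_t2_map.vtk",
                       point_scalars={"hotelling_t2": vertex_map})
        _write_json(checkpoint("shape_stats"), report["shape_stats"])

    # -- calcium --------------------------------------------------------
    if stage_enabled("calcium"):
        log.info("stage=calcium theta=%.2f", config.theta)
        maps = cohort.calcium_maps
        rates3d = cm.rate_map(maps)
        slabs_a = [cm.slab_average(m, "A") for m in maps]
        rate_a = cm.rate_map(slabs_a)
        sex_labels = (cohort.covariates["sex"] == "male").astype(int)
        z_sex, dr_sex = cm.z_map(slabs_a, sex_labels.to_numpy(),
                                 theta=config.theta)
        age_split, age_thr = cm.median_split(
            cohort.covariates["age"].to_numpy())
        z_age, dr_age = cm.z_map(slabs_a, age_split, theta=config.theta)
        cusp_rows = [cm.cusp_quantify(m, cohort.frame) for m in maps]
        cusp_mean = {lab: float(np.mean([r[lab]["volume_mm3"]
                                         for r in cusp_rows]))
                     for lab in ("NCC", "LCC", "RCC", "wall")}
        dice = []
        for i in range(min(config.n_native, config.n)):
            vol, affine = cohort.native_calcium(i)
            back = cm.normalize_calcium(
                vol, affine, cohort.trajectory(i),
                template_shape=maps[i].data.shape,
                template_origin=maps[i].origin)
            a = maps[i].data > 0
            b = back.data > 0
            inter = np.logical_and(a, b).sum()
            dice.append(2.0 * inter / max(a.sum() + b.sum(), 1))
        report["calcium"] = {
            "exceedance_mm3": {
                "rate>0.25": cm.exceedance_volume(rates3d, 0.25),
                "rate>0.50": cm.exceedance_volume(rates3d, 0.50)},
            "cusp_volumes_mm3": cusp_mean,
            "sex_zmap_max": float(z_sex.max()),
            "age_split_threshold": age_thr,
            "age_zmap_max": float(z_age.max()),
            "roundtrip_dice": [float(d) for d in dice],
        }
        cal_dir = out / "calcium"
        tio.write_volume(rates3d, maps[0].origin, cal_dir / "rate_map.nii.gz")
        np.savetxt(cal_dir / "rate_slice_A.csv", rate_a, delimiter=",")
        np.savetxt(cal_dir / "z_sex_slice_A.csv", z_sex, delimiter=",")
        _write_json(checkpoint("calcium"), report["calcium"])

    # -- clinical -------------------------------------------------------
    if stage_enabled("clinical"):
        log.info("stage=clinical")
        cov = cohort.covariates
        sub = cov[["age", "sex", "bsa", "bmi", "hypertension",
                   "coronary_disease", "euroscore", "frailty",
                   "annulus_mm", "sov_mm", "stj_mm", "aao_mm",
                   "rca_height_mm", "lca_height_mm", "calcium_volume_mm3",
                   "stroke_volume", "ejection_fraction",
                   "pressure_gradient"]].copy()
        sub["sex"] = (cov["sex"] == "male").astype(int)
        assoc = cs.pairwise_associations(sub)
        pvl_obs = cov["pvl"].dropna()
        counts = [int((pvl_obs == g).sum()) for g in cs.PVL_GRADES]
        summary = cs.grade_summary(counts) if sum(counts) else None
        model_tab = cov.dropna(subset=["device_size"]).copy()
        model_tab["sex_num"] = (model_tab["sex"] == "male").astype(int)
        model_tab["small_device"] = (
            model_tab["device_size"] <= model_tab["device_size"].median()
        ).astype(int)
        try:
            _, coefs = cs.device_choice_model(
                model_tab, "small_device",
                ["annulus_mm", "sov_mm", "sex_num", "calcium_volume_mm3"])
            device = {"coefficients": coefs["coef"].to_dict(),
                      "calcium_sign": float(
                          np.sign(coefs.loc["calcium_volume_mm3", "coef"]))}
        except ValueError as exc:
            device = {"error": str(exc)}
        report["clinical"] = {
            "bonferroni_threshold": cs.bonferroni_threshold(sub.shape[1]),
            "n_variables": sub.shape[1],
            "n_pairs_tested": int(len(assoc)),
            "pvl_summary": summary,
            "device_model": device,
        }
        (out / "clinical").mkdir(exist_ok=True)
        assoc.to_csv(out / "clinical" / "pairwise.csv", index=False)
        _write_json(checkpoint("clinical"), report["clinical"])

    report["elapsed_s"] = time.time() - t0
    _write_json(out / "report.json", report)
    return report


def _gt_atlas(cohort, config: PipelineConfig) -> AtlasModel:
    """Atlas view of the generator ground truth (for rendering/export)."""
    gt = cohort.ground_truth
    from .atlas import CurrentsKernel
    return AtlasModel(template=gt.template, grid=gt.grid,
                      momenta=[MomentaField(m) for m in gt.momenta],
                      deformation_kernel=gt.kernel,
                      currents_kernel=CurrentsKernel(config.lambda_w),
                      noise=config.noise)


def _load_atlas(atlas_dir, config: PipelineConfig, cohort) -> AtlasModel:
    """Rebuild an AtlasModel from a directory of momenta CSVs."""
    from .atlas import CurrentsKernel
    d = Path(atlas_dir)
    template = tio.read_mesh(d / "template.ply")
    files = sorted(d.glob("momenta_*.csv"))
    if not files:
        raise FileNotFoundError(f"no momenta files in {atlas_dir}")
    momenta, grid = [], None
    for f in files:
        mom, grid, _ = tio.read_momenta(f)
        momenta.append(mom)
    return AtlasModel(template=template, grid=grid, momenta=momenta,
                      deformation_kernel=DeformationKernel(config.lambda_v),
                      currents_kernel=CurrentsKernel(config.lambda_w),
                      noise=config.noise,
                      subject_ids=[f.stem.split("_", 1)[1] for f in files])
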