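"""End-to-end experiment runner.

Stages per trial: generate a stimulus, detect primary/secondary mirror
planes, pose it at its trial view, project into a (optionally noisy)
pair image, correct the image, run the four slant estimators, combine
them with the fitted (or configured) coefficients, and evaluate the
dissimilarities. Deterministic given the configured seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .combiner import (
    ModelCoefficients,
    ResponseRecord,
    TrialEstimates,
    fit_by_group,
    predict_slant,
    simulate_observer,
)
from .estimators import (
    select_slant_compactness,
    select_slant_two_planes,
    vanishing_point_slant,
)
from .evaluate import TrialResult, evaluate_trials, results_frame
from .family import FamilyGrid
from .imaging import Camera, angular_size, correct_to_orthographic, perturb_orientations
from .mesh import RigidPose
from .stimuli import (
    StimulusParams,
    Trial,
    generate_condition_set,
    manifest_rows,
    view_pose,
)
from .symmetry import (
    CorrespondenceSet,
    SymmetryPlane,
    select_primary_secondary,
    shared_vertices,
)

log = logging.getLogger("monoshape")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "n_per_slant": 2,
    "object_types": ["random", "rectangular"],
    "projections": ["orthographic", "perspective"],
    "stimulus": {},  # StimulusParams overrides
    "camera": {"viewing_distance": 50.8},
    # physical size scaling: stimuli are scaled so the mean image roughly
    # matches the experiment's angular sizes per projection
    "angular_size_target_deg": {"orthographic": 7.2, "perspective": 22.8},
    "noise_sd_deg": 1.0,
    "detection": "ransac",  # or "constructed" (use the generator's plane)
    "ransac": {"n_iters": 2000},
    "observer": {"beta": [0.0, 0.4, 0.3, 0.3], "t_deg": 75.0, "noise_deg": 2.0},
    "fit": {"enabled": True, "t_deg": 75.0},
}


def _merged_config(config: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for k, v in (config or {}).items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def _scale_for_angular_size(mesh_diameter: float, target_deg: float, distance: float) -> float:
    """Uniform scale factor putting the object's diameter at the target
    angular size when centered at the viewing distance."""
    want = 2.0 * distance * math.tan(math.radians(target_deg) / 2.0)
    return want / mesh_diameter


def _posed_trial(trial: Trial, scale: float, distance: float) -> RigidPose:
    """Pose centering the scaled object at (0, 0, distance)."""
    pose_r = view_pose(trial.view)
    center = trial.mesh.vertices.mean(axis=0) * scale
    t = np.array([0.0, 0.0, distance]) - pose_r.rotation @ center
    return RigidPose(pose_r.rotation, t)


def run_trial(
    trial: Trial,
    projection: str,
    cfg: dict,
    rng: np.random.Generator,
) -> TrialEstimates:
    """All estimator outputs for one trial."""
    distance = cfg["camera"]["viewing_distance"]
    target = cfg["angular_size_target_deg"][projection]
    scale = _scale_for_angular_size(trial.mesh.diameter(), target, distance)
    mesh = trial.mesh.copy()
    mesh.vertices = mesh.vertices * scale
    pose = _posed_trial(trial, scale, distance)
    camera = Camera(projection, distance)

    if cfg["detection"] == "constructed":
        from .stimuli import mirror_pairs

        plane = SymmetryPlane(np.array([1.0, 0.0, 0.0]), 0.0)
        primary = CorrespondenceSet(plane, mirror_pairs(mesh), 1e-9)
        _, secondary = select_primary_secondary(
            mesh,
            n_iters=cfg["ransac"]["n_iters"],
            seed=int(rng.integers(2**31)),
        )
    else:
        primary, secondary = select_primary_secondary(
            mesh,
            n_iters=cfg["ransac"]["n_iters"],
            seed=int(rng.integers(2**31)),
        )

    meta = {
        "trial_id": trial.trial_id,
        "object_type": trial.object_type,
        "slant_deg": trial.view.slant_deg,
        "tilt_deg": trial.view.tilt_deg,
        "seed": trial.seed,
    }
    from .imaging import project

    img1 = project(mesh, primary, pose, camera, meta)
    sd = cfg["noise_sd_deg"]
    img1n = perturb_orientations(img1, sd, seed=int(rng.integers(2**31)))
    gamma = angular_size(img1n)
    fam1 = FamilyGrid(correct_to_orthographic(img1n))
    th_c1 = select_slant_compactness(fam1, "c1")
    th_c2 = select_slant_compactness(fam1, "c2")
    shared = shared_vertices(primary, secondary)
    if len(secondary) >= 2 and len(shared) >= 3:
        img2 = project(mesh, secondary, pose, camera, meta)
        img2n = perturb_orientations(img2, sd, seed=int(rng.integers(2**31)))
        fam2 = FamilyGrid(correct_to_orthographic(img2n))
        th_sym2 = select_slant_two_planes(fam1, fam2, shared).value_deg
    else:
        # degenerate secondary support; the compactness estimate stands in
        th_sym2 = th_c1.value_deg
    th_persp = vanishing_point_slant(img1n).value_deg
    return TrialEstimates(
        theta_v2s3=th_c1.value_deg,
        theta_s3v=th_c2.value_deg,
        theta_sym2=th_sym2,
        theta_persp=th_persp,
        gamma_deg=gamma,
        trial_id=trial.trial_id,
        object_type=trial.object_type,
        projection=projection,
        slant_true_deg=trial.view.slant_deg,
    )


def estimates_frame(estimates: list[TrialEstimates]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(e) for e in estimates])
    return df.rename(
        columns={
            "theta_v2s3": "theta_v2s3_deg",
            "theta_s3v": "theta_s3v_deg",
            "theta_sym2": "theta_sym2_deg",
            "theta_persp": "theta_persp_deg",
        }
    )


def run_pipeline(config: dict | None = None, out_dir: str | Path | None = None):
    """Run the full simulated experiment; returns (estimates, records,
    predictions frame, summary) and optionally writes all interchange
    files under ``out_dir``."""
    cfg = _merged_config(config)
    rng = np.random.default_rng(cfg["seed"])
    params = StimulusParams(**cfg["stimulus"])
    t0 = time.time()
    all_estimates: list[TrialEstimates] = []
    all_trials: list[Trial] = []
    for otype in cfg["object_types"]:
        trials = generate_condition_set(
            cfg["n_per_slant"], otype, params, seed=cfg["seed"]
        )
        all_trials.extend(trials)
        log.info("generated %d %s trials", len(trials), otype)
        for projection in cfg["projections"]:
            for trial in trials:
                est = run_trial(trial, projection, cfg, rng)
                all_estimates.append(est)
            log.info(
                "estimated %s/%s (%d trials, %.1fs elapsed)",
                otype, projection, len(trials), time.time() - t0,
            )
    obs = cfg["observer"]
    truth_coef = ModelCoefficients(*obs["beta"], t_deg=obs["t_deg"])
    records = simulate_observer(
        all_estimates, truth_coef, obs["noise_deg"], seed=cfg["seed"] + 1
    )
    if cfg["fit"]["enabled"]:
        fits = fit_by_group(records, keys=("object_type",), t_deg=cfg["fit"]["t_deg"])
    else:
        fits = {}
    results = []
    for rec in records:
        est = rec.estimates
        coef = fits.get((est.object_type,), (truth_coef, {}))[0]
        pred = predict_slant(est, coef)
        results.append(
            TrialResult(
                est.trial_id,
                est.object_type,
                est.projection,
                est.slant_true_deg,
                pred,
                rec.response_slant_deg,
            )
        )
    summary = evaluate_trials(results)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(manifest_rows(all_trials)).to_csv(out / "manifest.csv", index=False)
        estimates_frame(all_estimates).to_csv(out / "estimates.csv", index=False)
        resp = estimates_frame([r.estimates for r in records])
        resp["response_slant_deg"] = [r.response_slant_deg for r in records]
        resp["subject"] = [r.subject for r in records]
        resp.to_csv(out / "responses.csv", index=False)
        results_frame(results).to_csv(out / "predictions.csv", index=False)
        summary.per_condition.to_csv(out / "summary_conditions.csv", index=False)
        summary.per_slant.to_csv(out / "summary_per_slant.csv", index=False)
        summary.correlations.to_csv(out / "summary_correlations.csv", index=False)
        fit_json = {
            "/".join(g): {
                "beta0": c.beta0, "beta1": c.beta1, "beta2": c.beta2,
                "beta3": c.beta3, "t_deg": c.t_deg, **d,
            }
            for g, (c, d) in fits.items()
        }
        (out / "fitted_models.json").write_text(json.dumps(fit_json, indent=1))
        cfg_text = yaml.safe_dump(cfg, sort_keys=True)
        manifest = {
            "version": __version__,
            "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
            "n_trials": len(all_estimates),
            "elapsed_s": round(time.time() - t0, 2),
        }
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
        (out / "config.yaml").write_text(cfg_text)
    return all_estimates, records, results_frame(results), summary
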