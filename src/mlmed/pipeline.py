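"""Stage orchestration over a study directory.

Each stage reads the previous stage's on-disk outputs (BIDS-style events TSV,
NIfTI volumes, motion text files) and writes its own, so any stage can be
rerun in isolation; all randomness is seeded from the run configuration.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import fit_random_intercept_lmm, paired_contrast
from .config import RunConfig
from .glm import build_single_trial_design, estimate_betas
from .mediation import (ThresholdSpec, PathMatrix, bootstrap_inference,
                        classify_mediation, fit_subject_paths,
                        prepare_mediation_inputs, small_volume_correct,
                        threshold_and_cluster, voxelwise_mediation)
from .moderation import moderate_path, sphere_average
from .synth import (BoldRun, draw_subject_params, simulate_blind_ratings,
                    simulate_subject)
from .volumes import (read_events, read_manifest, read_motion, read_volume,
                      write_events, write_manifest, write_motion, write_volume)


def _subject_label(i: int) -> str:
    return f"sub-{i + 1:02d}"


def _subject_dirs(cfg: RunConfig, outdir: Path) -> list[Path]:
    return [outdir / _subject_label(i) for i in range(cfg.n_subjects)]


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing {path}; run the '{stage}' stage first")
    return path


def _update_manifest(outdir: Path, section: str, payload: dict) -> dict:
    path = outdir / "manifest.json"
    manifest = read_manifest(path) if path.exists() else {}
    manifest[section] = payload
    write_manifest(path, manifest)
    return manifest


def simulate_stage(cfg: RunConfig, outdir) -> dict:
    """Generate the full synthetic study: events, BOLD, motion, moderators."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = draw_subject_params(cfg.sim, cfg.n_subjects, cfg.seed_simulate)
    blind_rows = []
    for i, (p, subdir) in enumerate(zip(params, _subject_dirs(cfg, outdir))):
        subdir.mkdir(exist_ok=True)
        data = simulate_subject(cfg.design, p, cfg.sim,
                                seed=cfg.seed_simulate + 100 * (i + 1))
        trials = data["trials"].copy()
        trials["duration"] = cfg.design.tasting_duration_s
        trials["trial_type"] = [f"price{a}_pay{b}" for a, b in
                                zip(trials["price"], trials["payment"])]
        trials = trials.rename(columns={"onset_s": "onset"})
        write_events(subdir / "events.tsv",
                     trials[["onset", "duration", "trial_type", "trial_index",
                             "run", "price", "payment", "wine", "rating"]])
        for run, motion in zip(data["bold"], data["motion"]):
            write_volume(subdir / f"bold_run-{run.run}.nii.gz", run.data, run.affine)
            write_motion(subdir / f"motion_run-{run.run}.txt", motion)
        blind = simulate_blind_ratings(p, cfg.sim,
                                       seed=cfg.seed_simulate + 100 * (i + 1) + 7)
        for wine, rating in enumerate(blind, start=1):
            blind_rows.append({"subject": _subject_label(i), "wine": wine,
                               "rating": rating})
    pd.DataFrame(blind_rows).to_csv(outdir / "blind.tsv", sep="\t", index=False)
    pd.DataFrame({
        "subject": [_subject_label(i) for i in range(cfg.n_subjects)],
        "w": [p.moderator_w_i for p in params],
    }).to_csv(outdir / "moderator.tsv", sep="\t", index=False)
    truth = {
        "true_indirect_effect": cfg.sim.true_indirect_effect,
        "subject_params": [dataclasses.asdict(p) for p in params],
        "seed": cfg.seed_simulate,
    }
    write_manifest(outdir / "truth.json", truth)
    _update_manifest(outdir, "simulate",
                     {"n_subjects": cfg.n_subjects, "seed": cfg.seed_simulate,
                      "n_trials": cfg.design.n_trials})
    return truth


def _load_subject_bold(subdir: Path):
    runs = []
    motions = []
    r = 1
    while (subdir / f"bold_run-{r}.nii.gz").exists():
        data, affine = read_volume(subdir / f"bold_run-{r}.nii.gz")
        runs.append(BoldRun(data=np.asarray(data, dtype=float), tr_s=2.5,
                            run=r, affine=affine))
        motions.append(read_motion(subdir / f"motion_run-{r}.txt"))
        r += 1
    if not runs:
        raise FileNotFoundError(f"no BOLD runs under {subdir}")
    return runs, motions


def glm_stage(cfg: RunConfig, outdir) -> list[Path]:
    """Single-trial GLM per subject: beta series NIfTI + per-trial QC table."""
    outdir = Path(outdir)
    written = []
    for subdir in _subject_dirs(cfg, outdir):
        events = read_events(_require(subdir / "events.tsv", "simulate"))
        runs, motions = _load_subject_bold(subdir)
        run_lengths = [r.n_scans for r in runs]
        trials = events.rename(columns={"onset": "onset_s"})
        design = build_single_trial_design(
            trials, tr_s=runs[0].tr_s, run_lengths=run_lengths,
            motion6=np.vstack(motions), duration_s=cfg.glm_duration_s,
            hrf=cfg.sim.hrf)
        bold2d = np.vstack([r.data2d for r in runs])
        series = estimate_betas(bold2d, design, vif_threshold=cfg.vif_threshold)
        beta4d = series.betas.T.reshape(*cfg.sim.grid_shape, -1)
        write_volume(subdir / "betas.nii.gz", beta4d, runs[0].affine)
        qc = pd.DataFrame({"trial_index": events["trial_index"],
                           "vif": series.vif, "included": series.included})
        qc.to_csv(subdir / "qc.tsv", sep="\t", index=False)
        written.append(subdir / "betas.nii.gz")
    _update_manifest(outdir, "glm", {"duration_s": cfg.glm_duration_s,
                                     "vif_threshold": cfg.vif_threshold})
    return written


def mediate_stage(cfg: RunConfig, outdir, n_boot: int | None = None) -> dict:
    """Voxelwise two-level mediation, thresholding, SVC and ROI path tables."""
    outdir = Path(outdir)
    n_boot = n_boot or cfg.n_boot
    grid = cfg.sim.grid()
    subject_data = []
    roi_mediators = {roi.name: [] for roi in cfg.rois}
    for subdir in _subject_dirs(cfg, outdir):
        events = read_events(_require(subdir / "events.tsv", "simulate"))
        beta4d, _ = read_volume(_require(subdir / "betas.nii.gz", "glm"))
        qc = pd.read_csv(subdir / "qc.tsv", sep="\t")
        M = np.asarray(beta4d, dtype=float).reshape(-1, beta4d.shape[-1]).T
        x, Mk, y, cov = prepare_mediation_inputs(
            events, M, ratings=events["rating"], x_coding=cfg.x_coding,
            included=qc["included"].to_numpy())
        subject_data.append((x, Mk, y, cov))
        # sphere-averaged mediator per ROI for the scalar path tables
        for roi in cfg.rois:
            from .volumes import make_sphere
            sphere = make_sphere(roi.center_mm, cfg.svc_radius_mm, grid)
            flat = np.ravel_multi_index(sphere.voxels.T, cfg.sim.grid_shape)
            roi_mediators[roi.name].append((x, Mk[:, flat].mean(axis=1), y, cov))

    maps = voxelwise_mediation(subject_data, n_boot=n_boot,
                               seed=cfg.seed_mediate, shape=cfg.sim.grid_shape)
    for path in ("a", "b", "ab", "cprime"):
        for fld in ("estimate", "p", "z"):
            write_volume(outdir / f"{path}_{fld}.nii.gz",
                         maps.volume(fld, path), grid.affine)

    tspec = ThresholdSpec(voxel_p=cfg.voxel_p, cluster_extent=cfg.cluster_extent,
                          connectivity=cfg.connectivity,
                          svc_radius_mm=cfg.svc_radius_mm, svc_alpha=cfg.svc_alpha)
    _, clusters = threshold_and_cluster(maps, tspec, path="ab", grid=grid)
    clusters.to_csv(outdir / "clusters_ab.tsv", sep="\t", index=False)

    svc_results = []
    for roi in cfg.rois:
        res = small_volume_correct(maps, roi.center_mm, grid,
                                   radius_mm=cfg.svc_radius_mm,
                                   alpha=cfg.svc_alpha, path="ab")
        res["name"] = roi.name
        res["classification"] = classify_mediation(maps, res["peak_voxel"],
                                                   alpha=cfg.svc_alpha)
        svc_results.append(res)
        rows = [fit_subject_paths(x, m, y, cov)
                for x, m, y, cov in roi_mediators[roi.name]]
        pm = PathMatrix.from_rows(rows)
        pd.DataFrame(pm.data, columns=["a", "b", "c", "cprime", "ab"]).to_csv(
            outdir / f"roi_paths_{roi.name}.tsv", sep="\t", index=False)

    payload = {
        "seed": cfg.seed_mediate, "n_boot": n_boot, "x_coding": cfg.x_coding,
        "voxel_p": cfg.voxel_p, "cluster_extent": cfg.cluster_extent,
        "connectivity": cfg.connectivity,
        "dropped_subject_voxels": maps.dropped_subject_voxels,
        "clusters_ab": clusters.to_dict(orient="records"),
        "svc": svc_results,
    }
    _update_manifest(outdir, "mediate", payload)
    return payload


def moderate_stage(cfg: RunConfig, outdir) -> dict:
    """Second-level moderation of ROI path coefficients by the moderator."""
    outdir = Path(outdir)
    w = pd.read_csv(_require(outdir / "moderator.tsv", "simulate"), sep="\t")
    results = []
    for roi in cfg.rois:
        paths = pd.read_csv(
            _require(outdir / f"roi_paths_{roi.name}.tsv", "mediate"), sep="\t")
        pm = PathMatrix(paths[["a", "b", "c", "cprime", "ab"]].to_numpy())
        res = moderate_path(pm, w, path=cfg.moderation_path,
                            n_boot=cfg.moderation_n_boot, seed=cfg.seed_moderate)
        res["name"] = roi.name
        results.append(res)
    payload = {"seed": cfg.seed_moderate, "results": results}
    _update_manifest(outdir, "moderate", payload)
    return payload


def behavior_stage(cfg: RunConfig, outdir) -> dict:
    """Rating mixed model and the informed-vs-blind paired contrast."""
    outdir = Path(outdir)
    tables = []
    for i, subdir in enumerate(_subject_dirs(cfg, outdir)):
        ev = read_events(_require(subdir / "events.tsv", "simulate"))
        ev["subject"] = _subject_label(i)
        tables.append(ev)
    table = pd.concat(tables, ignore_index=True)
    fit = fit_random_intercept_lmm(table)
    fit.fixed.to_csv(outdir / "behavior_lmm.tsv", sep="\t", index=False)

    blind = pd.read_csv(_require(outdir / "blind.tsv", "simulate"), sep="\t")
    blind_means = blind.groupby("subject")["rating"].mean()
    lo = table[table["price"] == 1].groupby("subject")["rating"].mean()
    hi = table[table["price"] == table["price"].max()].groupby("subject")["rating"].mean()
    subj = sorted(set(blind_means.index))
    contrast = paired_contrast((lo - blind_means).loc[subj].to_numpy(),
                               (hi - blind_means).loc[subj].to_numpy())
    payload = {
        "lmm": {"n_obs": fit.n_obs, "aic": fit.aic, "bic": fit.bic,
                "loglik": fit.loglik, "deviance": fit.deviance,
                "random_intercept_sd": fit.random_intercept_sd,
                "residual_sd": fit.residual_sd,
                "fixed": fit.fixed.to_dict(orient="records")},
        "informed_vs_blind": contrast,
    }
    _update_manifest(outdir, "behavior", payload)
    return payload


def report_stage(cfg: RunConfig, outdir) -> str:
    """Assemble a human-readable summary from the manifest."""
    outdir = Path(outdir)
    manifest = read_manifest(_require(outdir / "manifest.json", "simulate"))
    lines = ["study summary", "============="]
    if "mediate" in manifest:
        med = manifest["mediate"]
        lines.append(f"\nindirect-effect (a*b) clusters "
                     f"(p<{med['voxel_p']}, k>={med['cluster_extent']}):")
        lines.append(f"{'cluster':>8}{'size':>6}{'peak':>16}{'z':>8}")
        for c in med["clusters_ab"]:
            peak = f"({c['peak_i']},{c['peak_j']},{c['peak_k']})"
            lines.append(f"{c['cluster']:>8}{c['size']:>6}{peak:>16}"
                         f"{c['peak_z']:>8.2f}")
        lines.append("\nsmall-volume correction (Bonferroni in 10-mm spheres):")
        for r in med["svc"]:
            lines.append(f"  {r['name']}: p_corr={r['p_corrected']:.4f} "
                         f"({'sig' if r['significant'] else 'ns'}), "
                         f"mediation={r['classification']}")
    if "moderate" in manifest:
        for r in manifest["moderate"]["results"]:
            lines.append(f"\nmoderation of path {r['path']} at {r['name']}: "
                         f"gamma1={r['gamma1']:.3f}, p={r['p_gamma1']:.4f}")
    if "behavior" in manifest:
        beh = manifest["behavior"]
        price = next(t for t in beh["lmm"]["fixed"] if t["term"] == "price")
        lines.append(f"\nbehavior: price beta={price['beta']:.3f} "
                     f"(SE {price['se']:.3f}, p={price['p']:.2g}); "
                     f"informed-vs-blind t({beh['informed_vs_blind']['df']})="
                     f"{beh['informed_vs_blind']['t']:.2f}")
    text = "\n".join(lines) + "\n"
    (outdir / "summary.txt").write_text(text)
    return text
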