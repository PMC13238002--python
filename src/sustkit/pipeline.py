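"""End-to-end orchestration: cohort -> w-scores -> model fit / selection ->
longitudinal assignment and consistency -> statistics -> survival.

Configuration comes from YAML (synthetic mode or ingest mode with CSV
paths).  A single global seed is fanned out to per-stage seeds through
``numpy.random.SeedSequence(seed).spawn`` in a fixed stage order
(simulate, fit, cv), so each stage is independently reproducible.  Model
fitting sees baseline rows only; staging sees every visit.  Ground truth
is written for evaluation but never read by any analysis stage.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import longitudinal as longi
from . import survival as surv
from .events import build_events
from .synthetic import (GeneratorConfig, generate_cohort, simulate_survival,
                        write_cohort)
from .sustain import (assign_subjects, cross_validate_cvic, fit_sustain,
                      positional_variance)
from .wscore import compute_wscores, fit_reference

__all__ = ["RunManifest", "run_pipeline", "load_config", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "sustkit_run",
    "mode": "synthetic",            # synthetic | ingest
    "synthetic": {},                 # GeneratorConfig overrides
    "ingest": {},                    # hc_csv / patients_csv / survival_csv
    "model": {
        "thresholds": [1.0, 2.0],
        "zmax_rule": "auto",
        "max_k": 3,
        "run_cv": False,
        "n_folds": 8,
        "n_startpoints": 10,
        "split_startpoints": 2,
        "n_split_restarts": 3,
        "em_tol": 1e-6,
        "mcmc_iters": 10000,
    },
    "clinical_features": ["alsfrs_total", "fvc", "umn_burden", "lmn_burden",
                          "finger_tapping", "foot_tapping", "ecas_total"],
    "baseline_variables": {"age_bl": "continuous", "education_years": "continuous",
                           "sex": "binary", "onset_bulbar": "binary"},
}


@dataclass
class RunManifest:
    config: dict
    seeds: dict
    outputs: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    warnings_log: list = field(default_factory=list)
    completed: bool = False
    failed_stage: str | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "config": self.config, "seeds": self.seeds,
                "outputs": self.outputs, "timings": self.timings,
                "warnings": self.warnings_log, "completed": self.completed,
                "failed_stage": self.failed_stage,
            }, fh, indent=1, default=str)


def load_config(path_or_dict) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path_or_dict is None:
        return cfg
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict)
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _stage_seeds(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(3)
    names = ("simulate", "fit", "cv")
    return {name: int(child.generate_state(1)[0]) for name, child in zip(names, children)}


def run_pipeline(config=None) -> RunManifest:
    """Execute all stages in order; any failure aborts with the stage name
    recorded in the (partial) manifest."""
    cfg = load_config(config)
    seeds = _stage_seeds(int(cfg["seed"]))
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, seeds=seeds)
    stage = "init"
    t_all = time.time()
    try:
        with warnings.catch_warnings(record=True) as wrec:
            warnings.simplefilter("always")

            stage = "data"
            t0 = time.time()
            hc, patients, survival_raw = _load_or_simulate(cfg, seeds, outdir, manifest)
            manifest.timings["data"] = time.time() - t0

            stage = "wscore"
            t0 = time.time()
            from .synthetic import MODEL_ROIS
            rois = [r for r in MODEL_ROIS if r in hc.columns]
            ref = fit_reference(hc, rois)
            w_hc = compute_wscores(hc, ref)
            w_pt = compute_wscores(patients, ref)
            ref.to_json(outdir / "reference_model.json")
            w_pt.to_csv(outdir / "wscores_patients.csv", index=False)
            w_hc.to_csv(outdir / "wscores_hc.csv", index=False)
            manifest.outputs.update({
                "reference_model": str(outdir / "reference_model.json"),
                "wscores_patients": str(outdir / "wscores_patients.csv"),
                "wscores_hc": str(outdir / "wscores_hc.csv")})
            manifest.timings["wscore"] = time.time() - t0

            stage = "fit"
            t0 = time.time()
            mcfg = cfg["model"]
            w_bl = w_pt[w_pt["visit"] == 1]
            event_set = build_events(rois, tuple(mcfg["thresholds"]),
                                     zmax_rule=mcfg["zmax_rule"], patient_wscores=w_bl)
            X_bl = event_set.to_model_scale(w_bl)
            cv_res = None
            if mcfg["run_cv"]:
                cv_res = cross_validate_cvic(
                    X_bl, event_set, max_subtypes=mcfg["max_k"],
                    n_folds=mcfg["n_folds"], seed=seeds["cv"],
                    n_startpoints=mcfg["n_startpoints"],
                    em_tol=mcfg["em_tol"], mcmc_iters=mcfg["mcmc_iters"],
                    n_split_restarts=mcfg["n_split_restarts"],
                    split_startpoints=mcfg["split_startpoints"])
                with open(outdir / "cvic.json", "w") as fh:
                    json.dump(cv_res.to_dict(), fh, indent=1)
                manifest.outputs["cvic"] = str(outdir / "cvic.json")
            k_use = cv_res.selected_k if cv_res is not None else mcfg["max_k"]
            fits = fit_sustain(
                X_bl, event_set, max_subtypes=k_use,
                n_startpoints=mcfg["n_startpoints"], em_tol=mcfg["em_tol"],
                mcmc_iters=mcfg["mcmc_iters"], seed=seeds["fit"],
                n_split_restarts=mcfg["n_split_restarts"],
                split_startpoints=mcfg["split_startpoints"])
            fit = fits[-1]
            with open(outdir / "model.json", "w") as fh:
                json.dump(fit.to_dict(), fh, indent=1)
            pvd = positional_variance(fit)
            for c, mat in enumerate(pvd):
                pd.DataFrame(mat, index=[f"{e.biomarker}:z{e.threshold:g}"
                                         for e in event_set.events]).to_csv(
                    outdir / f"pvd_subtype{c + 1}.csv")
            manifest.outputs["model"] = str(outdir / "model.json")
            manifest.timings["fit"] = time.time() - t0

            stage = "longitudinal"
            t0 = time.time()
            visits = longi.stage_followups(fit, w_pt)
            report = longi.classify_consistency(visits)
            longi.compare_confidence(report)
            resolved = longi.resolve_final_subtype(visits)
            resolved.to_csv(outdir / "assignments.csv", index=False)
            report.cases.to_csv(outdir / "consistency_cases.csv", index=False)
            with open(outdir / "consistency.json", "w") as fh:
                json.dump(report.to_dict(), fh, indent=1, default=float)
            manifest.outputs.update({
                "assignments": str(outdir / "assignments.csv"),
                "consistency": str(outdir / "consistency.json"),
                "consistency_cases": str(outdir / "consistency_cases.csv")})
            manifest.timings["longitudinal"] = time.time() - t0

            stage = "stats"
            t0 = time.time()
            stats_group = _group_stats(cfg, hc, patients, w_hc, w_pt, rois)
            stats_group.to_csv(outdir / "stats_group.csv", index=False)
            stats_stage = _stage_stats(cfg, patients, w_pt, resolved, rois)
            stats_stage.to_csv(outdir / "stats_stage.csv", index=False)
            manifest.outputs.update({
                "stats_group": str(outdir / "stats_group.csv"),
                "stats_stage": str(outdir / "stats_stage.csv")})
            manifest.timings["stats"] = time.time() - t0

            stage = "survival"
            t0 = time.time()
            if survival_raw is not None:
                followup = visits.groupby("subject_id").size()
                followup = set(followup[followup >= 2].index)
                finals = resolved[["subject_id", "final_subtype"]].drop_duplicates()
                records = surv.build_survival_records(
                    survival_raw, finals, followup_subjects=followup)
                records.to_csv(outdir / "survival_records.csv", index=False)
                km_rows = []
                for g, grp in records.groupby("group"):
                    table, med = surv.kaplan_meier(grp)
                    table.insert(0, "group", g)
                    km_rows.append(table.assign(median=med))
                pd.concat(km_rows).to_csv(outdir / "km_curves.csv", index=False)
                lr = {}
                if records["group"].nunique() >= 2:
                    lr["omnibus"] = surv.logrank_test(records).to_dict(orient="records")
                    lr["pairwise"] = surv.logrank_test(
                        records, pairwise=True).to_dict(orient="records")
                with open(outdir / "logrank.json", "w") as fh:
                    json.dump(lr, fh, indent=1)
                manifest.outputs.update({
                    "survival_records": str(outdir / "survival_records.csv"),
                    "km_curves": str(outdir / "km_curves.csv"),
                    "logrank": str(outdir / "logrank.json")})
            manifest.timings["survival"] = time.time() - t0

        manifest.warnings_log = [str(w.message) for w in wrec]
        manifest.completed = True
    except Exception:
        manifest.failed_stage = stage
        manifest.to_json(outdir / "manifest.json")
        raise
    manifest.timings["total"] = time.time() - t_all
    manifest.to_json(outdir / "manifest.json")
    manifest.outputs["manifest"] = str(outdir / "manifest.json")
    return manifest


def _load_or_simulate(cfg, seeds, outdir, manifest):
    if cfg["mode"] == "synthetic":
        gen_kwargs = dict(cfg["synthetic"])
        gen_kwargs["seed"] = seeds["simulate"]
        gcfg = GeneratorConfig(**gen_kwargs)
        from .synthetic import MODEL_ROIS
        event_set = build_events(MODEL_ROIS, tuple(cfg["model"]["thresholds"]),
                                 zmax_rule=3.0)
        hc, patients, truth = generate_cohort(gcfg, event_set)
        survival_raw = simulate_survival(truth, gcfg)
        paths = write_cohort(outdir, hc, patients, survival_raw, truth)
        manifest.outputs.update(paths)
        return hc, patients, survival_raw
    if cfg["mode"] == "ingest":
        ing = cfg["ingest"]
        hc = pd.read_csv(ing["hc_csv"])
        patients = pd.read_csv(ing["patients_csv"])
        survival_raw = (pd.read_csv(ing["survival_csv"])
                        if ing.get("survival_csv") else None)
        return hc, patients, survival_raw
    raise ValueError(f"unknown mode {cfg['mode']!r}")


def _group_stats(cfg, hc, patients, w_hc, w_pt, rois) -> pd.DataFrame:
    """ALS-vs-HC contrasts: clinical LME family + imaging LME family,
    BH-corrected independently per family."""
    clin = pd.concat([hc, patients], ignore_index=True)
    clin["Dx"] = (clin["group"] == "ALS").astype(int)
    frames = []
    for feat in cfg["clinical_features"]:
        if feat not in clin.columns:
            continue
        spec = assoc.StatModelSpec(response=feat, covariates=("age_bl", "sex"),
                                   family_label="clinical")
        frames.append(assoc.fit_group_lme(spec, clin).assign(response=feat))
    imaging = pd.concat([w_hc.assign(Dx=0), w_pt.assign(Dx=1)], ignore_index=True)
    for roi in rois:
        spec = assoc.StatModelSpec(response=roi, covariates=(),
                                   family_label="imaging")
        frames.append(assoc.fit_group_lme(spec, imaging).assign(response=roi))
    out = pd.concat(frames, ignore_index=True)
    return assoc.fdr_correct(out)


def _stage_stats(cfg, patients, w_pt, resolved, rois) -> pd.DataFrame:
    """Stage associations per subtype and pooled, one global FDR family."""
    stages = resolved[["subject_id", "visit", "ml_stage", "final_subtype"]].rename(
        columns={"ml_stage": "stage"})
    clin = patients.merge(stages, on=["subject_id", "visit"])
    img = w_pt.merge(stages, on=["subject_id", "visit"])
    subsets = [("all", None)] + [(s, s) for s in sorted(resolved["final_subtype"].unique())
                                 if s != "S0"]
    frames = []
    for name, sel in subsets:
        csub = clin if sel is None else clin[clin["final_subtype"] == sel]
        isub = img if sel is None else img[img["final_subtype"] == sel]
        for feat in cfg["clinical_features"]:
            if feat not in csub.columns or len(csub) < 10:
                continue
            covs = ("age_bl", "sex", "education_years") if feat == "ecas_total" \
                else ("age_bl", "sex")
            frames.append(assoc.fit_stage_association(
                csub, feat, longitudinal=True, covariates=covs,
                family_label="global").assign(response=feat, subset=name))
        for roi in rois:
            if len(isub) < 10:
                continue
            frames.append(assoc.fit_stage_association(
                isub, roi, longitudinal=True, covariates=(),
                family_label="global").assign(response=roi, subset=name))
    out = pd.concat(frames, ignore_index=True)
    return assoc.fdr_correct(out)
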