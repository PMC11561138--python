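"""End-to-end experiment orchestration: simulate -> estimate -> train ->
predict -> evaluate, with a reproducible artefact directory.

Every stage communicates through files only, so each stage can also be run
in isolation (see the CLI). A manifest records the configuration hash and
package version; a completed stage whose outputs match the manifest hash is
skipped on re-run, which makes partially failed runs resumable. All
randomness funnels through the single root seed in the configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from . import imu_pipeline as ip
from . import prediction_models as pm
from . import video_pipeline as vp
from .evaluation import (
    build_balanced_test_set,
    compute_peak_metrics,
    compute_predictor_metrics,
    mae_change_from_baseline,
)
from .gait_features import RESPONSE_VARIABLES, extract_loading_peaks
from .synthetic import (
    GenerativeLoadModel,
    generate_training_table,
    get_noise_profile,
    sample_cohort,
    sample_koa_cohort,
    simulate_trials,
)

log = logging.getLogger("kneeload")

MODALITIES = ("baseline", "imu", "vc")


class RunConfig(BaseModel):
    """Declarative configuration of one end-to-end experiment."""

    seed: int = 1
    n_test_subjects: int = 20
    n_train_subjects: int = 100
    n_koa_subjects: int = 40
    trials_per_config: int = 10
    train_trials_per_subject: int = 18
    noise_profile: str = "realistic"
    predictor_set: str = "full"
    modalities: list[str] = Field(default_factory=lambda: list(MODALITIES))
    analyzed_leg: str = "right"

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def estimate_trial_predictors(trial, leg: str = "right") -> dict[str, float]:
    """Per-modality walking speed and KFA predictor for one trial.

    Baseline values are the simulator's ground truth (the stand-in for the
    laboratory reference pipeline); IMU/VC values come from the estimation
    pipelines. Estimator failures yield NaN, which downstream balancing
    treats as an invalid trial.
    """
    out = {
        "speed_baseline": trial.true_speed,
        "kfa_baseline": trial.kfa_predictor_truth,
        "speed_imu": np.nan,
        "kfa_imu": np.nan,
        "speed_vc": np.nan,
        "kfa_vc": np.nan,
    }
    if trial.imu is not None:
        try:
            out["speed_imu"] = ip.estimate_walking_speed_imu(
                trial.imu, trial.subject.height
            )
            out["kfa_imu"] = ip.estimate_kfa_predictor_imu(trial.imu, leg=leg)
        except Exception as exc:  # noqa: BLE001 - degraded trial, not a bug
            log.debug("IMU estimation failed: %s", exc)
    if trial.keypoints is not None:
        try:
            scale = vp.estimate_scale(trial.keypoints, trial.subject.height)
            out["speed_vc"] = vp.estimate_walking_speed_vc(trial.keypoints, scale)
            out["kfa_vc"] = vp.estimate_kfa_predictor_vc(trial.keypoints, leg=leg)
        except Exception as exc:  # noqa: BLE001
            log.debug("VC estimation failed: %s", exc)
    return out


def build_trial_table(config: RunConfig,
                      load_model: GenerativeLoadModel | None = None) -> pd.DataFrame:
    """Simulate the test cohort and estimate predictors for every trial."""
    noise = get_noise_profile(config.noise_profile)
    cohort = sample_cohort(config.n_test_subjects, config.seed)
    with_imu = "imu" in config.modalities
    with_vc = "vc" in config.modalities
    rows = []
    for trial in simulate_trials(
        cohort,
        config.trials_per_config,
        seed=config.seed + 1,
        load_model=load_model,
        noise=noise,
        with_imu=with_imu,
        with_video=with_vc,
    ):
        row = {
            "subject_id": trial.subject_id,
            "velocity_class": trial.velocity_class,
            "direction": trial.direction,
            "trial_index": trial.trial_index,
            "valid": trial.valid,
            "mass": trial.subject.mass,
            "height": trial.subject.height,
            "age": trial.subject.age,
            "sex": trial.subject.sex,
        }
        row.update(estimate_trial_predictors(trial, leg=config.analyzed_leg))
        peaks = extract_loading_peaks(trial.load.curves)
        for resp in RESPONSE_VARIABLES:
            row[f"ref_{resp}"] = peaks[resp]
        # A trial is only usable when every requested modality produced
        # estimates (mirrors restricting analysis to participants valid
        # for all modalities).
        needed = [f"speed_{m}" for m in config.modalities] + [
            f"kfa_{m}" for m in config.modalities
        ]
        row["valid"] = bool(row["valid"]) and all(
            np.isfinite(row[c]) for c in needed
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _predictor_frame(df: pd.DataFrame, modality: str) -> pd.DataFrame:
    out = df[["mass", "height", "age", "sex"]].copy()
    out["speed"] = df[f"speed_{modality}"]
    out["kfa"] = df[f"kfa_{modality}"]
    return out


def predict_peaks(
    models: dict[str, tuple[pm.AnnModel, pm.MlrModel]],
    trials: pd.DataFrame,
    modalities: list[str],
) -> pd.DataFrame:
    """Long-format predictions: one row per trial x modality x response."""
    rows = []
    for modality in modalities:
        x = _predictor_frame(trials, modality)
        for resp, (ann, mlr) in models.items():
            ann_pred = ann.predict(x)
            mlr_pred = mlr.predict(x)
            for i, (_, trial) in enumerate(trials.iterrows()):
                rows.append({
                    "subject_id": trial["subject_id"],
                    "velocity_class": trial["velocity_class"],
                    "direction": trial["direction"],
                    "trial_index": trial["trial_index"],
                    "modality": modality,
                    "response": resp,
                    "reference": trial[f"ref_{resp}"],
                    "ann": ann_pred[i],
                    "mlr": mlr_pred[i],
                })
    return pd.DataFrame(rows)


def evaluate_predictions(predictions: pd.DataFrame) -> pd.DataFrame:
    """Pooled accuracy per response x modality x model type."""
    rows = []
    for (modality, resp), g in predictions.groupby(["modality", "response"],
                                                   sort=True):
        for model_kind in ("ann", "mlr"):
            m = compute_peak_metrics(g[model_kind].to_numpy(),
                                     g["reference"].to_numpy())
            rows.append({
                "modality": modality, "response": resp, "model": model_kind,
                "rmse": m.rmse, "nrmse": m.nrmse, "r": m.r, "mae": m.mae,
                "n": m.n,
            })
    return pd.DataFrame(rows)


def per_subject_observations(predictions: pd.DataFrame) -> pd.DataFrame:
    """Long-format per-subject NRMSE table (input for repeated-measures
    statistics in external software)."""
    rows = []
    group_cols = ["subject_id", "modality", "response"]
    for (sid, modality, resp), g in predictions.groupby(group_cols, sort=True):
        ref = g["reference"].to_numpy()
        for model_kind in ("ann", "mlr"):
            err = g[model_kind].to_numpy() - ref
            rmse = float(np.sqrt(np.mean(err**2)))
            rows.append({
                "subject_id": sid, "modality": modality, "response": resp,
                "model": model_kind,
                "nrmse": rmse / ref.mean() if ref.mean() else np.nan,
            })
    return pd.DataFrame(rows)


def _stage_fresh(out: Path, stage: str, cfg_hash: str, files: list[Path]) -> bool:
    manifest = out / "manifest.json"
    if not manifest.exists() or not all(f.exists() for f in files):
        return False
    with open(manifest) as fh:
        state = json.load(fh)
    return state.get("stages", {}).get(stage) == cfg_hash


def _mark_stage(out: Path, stage: str, config: RunConfig) -> None:
    manifest = out / "manifest.json"
    state = {"package_version": __version__,
             "config": config.model_dump(),
             "config_hash": config.config_hash(),
             "stages": {}}
    if manifest.exists():
        with open(manifest) as fh:
            prev = json.load(fh)
        if prev.get("config_hash") == state["config_hash"]:
            state["stages"] = prev.get("stages", {})
    state["stages"][stage] = config.config_hash()
    with open(manifest, "w") as fh:
        json.dump(state, fh, indent=1, sort_keys=True)


def run_experiment(config: RunConfig, out_dir: Path) -> Path:
    """Run the full chained experiment into ``out_dir``.

    Identical configurations produce byte-identical outputs; completed
    stages are skipped when re-running after a partial failure.
    """
    out = Path(out_dir)
    (out / "data").mkdir(parents=True, exist_ok=True)
    (out / "models").mkdir(exist_ok=True)
    (out / "predictions").mkdir(exist_ok=True)
    (out / "report").mkdir(exist_ok=True)
    h = config.config_hash()

    trials_csv = out / "data" / "trials.csv"
    train_csv = out / "data" / "train.csv"
    koa_csv = out / "data" / "koa.csv"
    if not _stage_fresh(out, "data", h, [trials_csv, train_csv, koa_csv]):
        log.info("stage data: simulating %d test subjects", config.n_test_subjects)
        build_trial_table(config).to_csv(trials_csv, index=False)
        train_cohort = sample_cohort(config.n_train_subjects, config.seed + 10_000)
        generate_training_table(
            train_cohort, config.train_trials_per_subject, seed=config.seed + 2
        ).to_csv(train_csv, index=False)
        koa_cohort = sample_koa_cohort(config.n_koa_subjects, config.seed + 20_000)
        generate_training_table(
            koa_cohort, config.train_trials_per_subject, seed=config.seed + 3
        ).to_csv(koa_csv, index=False)
        _mark_stage(out, "data", config)
    else:
        log.info("stage data: up to date, skipping")

    models_json = out / "models" / "models.json"
    if not _stage_fresh(out, "models", h, [models_json]):
        log.info("stage models: training 9 ANN + 9 MLR models")
        train_df = pd.read_csv(train_csv)
        koa_df = pd.read_csv(koa_csv)
        models = pm.train_all_peaks(
            train_df,
            predictor_set=config.predictor_set,
            cfg=pm.TrainingConfig(seed=config.seed),
            pretrain_data=koa_df,
        )
        pm.save_models(models, models_json)
        _mark_stage(out, "models", config)
    else:
        log.info("stage models: up to date, skipping")

    predictions_csv = out / "predictions" / "predictions.csv"
    excluded_json = out / "predictions" / "excluded.json"
    if not _stage_fresh(out, "predictions", h, [predictions_csv, excluded_json]):
        log.info("stage predictions: balancing test set and predicting")
        trials = pd.read_csv(trials_csv)
        balanced, excluded = build_balanced_test_set(trials)
        models = pm.load_models(models_json)
        predict_peaks(models, balanced, config.modalities).to_csv(
            predictions_csv, index=False
        )
        with open(excluded_json, "w") as fh:
            json.dump({"excluded_subjects": excluded,
                       "n_kept": int(balanced["subject_id"].nunique())}, fh,
                      indent=1)
        _mark_stage(out, "predictions", config)
    else:
        log.info("stage predictions: up to date, skipping")

    metrics_csv = out / "report" / "metrics.csv"
    observations_csv = out / "report" / "observations.csv"
    predictor_csv = out / "report" / "predictor_metrics.csv"
    mae_csv = out / "report" / "mae_change.csv"
    if not _stage_fresh(out, "report", h,
                        [metrics_csv, observations_csv, predictor_csv]):
        log.info("stage report: computing metrics")
        predictions = pd.read_csv(predictions_csv)
        evaluate_predictions(predictions).to_csv(metrics_csv, index=False)
        per_subject_observations(predictions).to_csv(observations_csv, index=False)

        trials = pd.read_csv(trials_csv)
        balanced, _ = build_balanced_test_set(trials)
        rows = []
        for modality in config.modalities:
            if modality == "baseline":
                continue
            for predictor in ("speed", "kfa"):
                m = compute_predictor_metrics(
                    balanced, f"{predictor}_{modality}", f"{predictor}_baseline"
                )
                rows.append({"modality": modality, "predictor": predictor, **m})
        pd.DataFrame(rows).to_csv(predictor_csv, index=False)

        if {"baseline"} < set(config.modalities):
            wide = predictions.pivot_table(
                index=["subject_id", "velocity_class", "direction",
                       "trial_index", "response", "reference"],
                columns="modality", values="ann",
            ).reset_index()
            mae_rows = []
            for modality in config.modalities:
                if modality == "baseline":
                    continue
                for resp, g in wide.groupby("response"):
                    tab = mae_change_from_baseline(
                        g, modality, "baseline", "reference"
                    )
                    tab.insert(0, "response", resp)
                    tab.insert(0, "modality", modality)
                    mae_rows.append(tab)
            pd.concat(mae_rows).to_csv(mae_csv, index=False)
        _mark_stage(out, "report", config)
    else:
        log.info("stage report: up to date, skipping")
    return out
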