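"""End-to-end phantom experiment: simulate, pretrain, transfer, predict,
correct, explain, and compare — from one configuration.

Cohort roles mirror the study design and are disjoint by construction
(each role gets its own id prefix):

* ``pretrain``  — autoencoder training (with a held-out reconstruction
  validation split),
* ``train``     — age-regressor training,
* ``select``    — regressor checkpoint selection (validation MAE),
* ``correct``   — bias-correction fitting and noise calibration,
* ``clinical``  — the patient/control evaluation cohort.

One model is trained per modality channel.  Sensitivity maps are always
generated from the uncorrected model predictions; the bias correction
only ever touches the prediction table.
"""

from __future__ import annotations

import hashlib
import sys
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .brainage import (ancova_brainage, apply_bias_correction,
                       build_prediction_table, fit_bias_correction)
from .concordance import concordance_report
from .io import save_model, save_nifti, write_json
from .models import (NetSpec, TrainConfig, predict_age, select_best_checkpoint,
                     train_cae, train_regressor, transfer_encoder)
from .phantom import (AtlasSpec, EffectModel, GroundTruthManifest, build_atlas,
                      render_subject, sample_cohort, subject_intercept,
                      write_dataset)
from .roi_stats import build_roi_matrix, roi_ancova
from .saliency import SaliencyConfig, calibrate_noise, default_noise_grid, smoothgrad

__all__ = ["ExperimentConfig", "validate_config", "run_full_experiment",
           "rerun_concordance"]

_ROLES = ("pretrain", "train", "select", "correct", "clinical")


@dataclass(frozen=True)
class ExperimentConfig:
    # phantom
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    n_regions: int = 24
    n_disease_regions: int = 6
    n_channels: int = 2
    disease_extra_years: float = 40.0
    subject_sd: float = 0.05
    region_sd: float = 0.03
    voxel_sd: float = 0.05
    age_min: float = 18.0
    age_max: float = 88.0
    # cohort sizes per role
    n_pretrain: int = 60
    n_train: int = 100
    n_select: int = 20
    n_correct: int = 40
    n_clinical: int = 80
    clinical_patient_fraction: float = 0.5
    # model
    encoder_widths: tuple[int, ...] = (8, 16, 32)
    latent_dim: int = 64
    head_widths: tuple[int, ...] = (32,)
    cae_epochs: int = 12
    cae_selection_window: int = 8
    reg_epochs: int = 40
    reg_selection_window: int = 30
    batch_size: int = 16
    cae_learning_rate: float = 1e-3
    reg_learning_rate: float = 1e-2
    cae_val_fraction: float = 0.1
    # saliency
    saliency_n_samples: int = 25
    calib_n_samples: int = 8
    calib_max_subjects: int = 20
    # stats
    alpha: float = 0.05
    brainage_covariates: tuple[str, ...] = ("age", "sex")
    roi_covariates: tuple[str, ...] = ("age",)
    # bookkeeping
    seed: int = 0
    write_volumes: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("grid_shape", "encoder_widths", "head_widths",
                    "brainage_covariates", "roi_covariates"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


def validate_config(config: ExperimentConfig) -> list[str]:
    """Return a list of human-readable violations (empty iff valid)."""
    v: list[str] = []
    factor = 2 ** len(config.encoder_widths)
    if any(n % factor for n in config.grid_shape):
        v.append(f"grid_shape {config.grid_shape} not divisible by 2^"
                 f"{len(config.encoder_widths)} (encoder depth)")
    if config.n_regions < 1:
        v.append("n_regions must be >= 1")
    if config.n_disease_regions > config.n_regions:
        v.append("n_disease_regions exceeds n_regions")
    if config.cae_selection_window > config.cae_epochs:
        v.append(f"cae_selection_window ({config.cae_selection_window}) "
                 f"exceeds cae_epochs ({config.cae_epochs})")
    if config.reg_selection_window > config.reg_epochs:
        v.append(f"reg_selection_window ({config.reg_selection_window}) "
                 f"exceeds reg_epochs ({config.reg_epochs})")
    for role in _ROLES:
        if getattr(config, f"n_{role}") < 1:
            v.append(f"n_{role} must be >= 1")
    if not 0.0 < config.clinical_patient_fraction < 1.0:
        v.append("clinical_patient_fraction must lie strictly in (0, 1) so "
                 "both clinical groups are populated")
    if config.n_clinical < 4:
        v.append("n_clinical must be >= 4 (two groups of two)")
    if not 0.0 < config.alpha < 1.0:
        v.append("alpha must lie in (0, 1)")
    if config.age_min >= config.age_max:
        v.append("age_min must be < age_max")
    if not 0.0 < config.cae_val_fraction < 1.0:
        v.append("cae_val_fraction must lie in (0, 1)")
    if len(set(_ROLES)) != len(_ROLES):  # defensive; roles define id prefixes
        v.append("cohort roles must be distinct")
    return v


def _subseed(seed: int, tag: str) -> int:
    h = int(hashlib.sha256(f"{seed}:{tag}".encode()).hexdigest()[:8], 16)
    return h % (2 ** 31)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_experiment(config: ExperimentConfig, out_dir: str | Path,
                        log=print) -> dict:
    """Run the whole experiment; write all artifacts under ``out_dir``.

    Returns a results bundle (tables, reports, ground truth) for
    programmatic use.  Any stage failure raises with the stage name;
    artifacts written by completed stages are left in place.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    status = {"stage": "init"}
    try:
        return _run(config, out, log, status)
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        raise RuntimeError(
            f"pipeline failed in stage {status['stage']!r}: {exc}") from exc


def _run(config: ExperimentConfig, out: Path, log, status: dict) -> dict:
    seed = config.seed

    # ---- simulate -------------------------------------------------------
    status["stage"] = "simulate"
    log(f"[{status['stage']}] grid={config.grid_shape} K={config.n_regions} "
        f"seed={seed}")
    atlas_spec = AtlasSpec(grid_shape=tuple(config.grid_shape),
                           n_regions=config.n_regions,
                           seed=_subseed(seed, "atlas"))
    atlas, region_table = build_atlas(atlas_spec)
    effects = EffectModel.default(
        n_regions=config.n_regions, n_disease=config.n_disease_regions,
        n_channels=config.n_channels, seed=_subseed(seed, "effects"),
        disease_extra_years=config.disease_extra_years,
        subject_sd=config.subject_sd,
        region_sd=config.region_sd, voxel_sd=config.voxel_sd,
        age_ref=config.age_min)

    cohorts: dict[str, pd.DataFrame] = {}
    volumes: dict[str, np.ndarray] = {}
    render_seed = _subseed(seed, "render")
    for role in _ROLES:
        frac = config.clinical_patient_fraction if role == "clinical" else 0.0
        cohort = sample_cohort(getattr(config, f"n_{role}"), frac,
                               age_min=config.age_min, age_max=config.age_max,
                               seed=_subseed(seed, f"cohort:{role}"),
                               id_prefix=role)
        cohorts[role] = cohort
        for _, row in cohort.iterrows():
            volumes[row["participant_id"]] = render_subject(
                row, atlas, effects, seed=render_seed)

    all_cohort = pd.concat(
        [c.assign(role=role) for role, c in cohorts.items()],
        ignore_index=True)
    manifest_gt = GroundTruthManifest(
        effects=effects, atlas_spec=atlas_spec, seed=render_seed,
        intercepts={sid: subject_intercept(sid, render_seed, effects.subject_sd)
                    for sid in all_cohort["participant_id"]})
    if config.write_volumes:
        write_dataset(all_cohort, volumes, atlas, region_table,
                      manifest_gt, out / "dataset")
    else:
        save_nifti(out / "dataset" / "atlas.nii.gz", atlas)
        region_table.to_csv(out / "dataset" / "regions.tsv", sep="\t", index=False)
        all_cohort.to_csv(out / "dataset" / "participants.tsv", sep="\t",
                          index=False)
        write_json(out / "dataset" / "manifest.json", manifest_gt.to_dict())
    labels = region_table["label"].to_numpy()

    def stack_for(role: str, channel: int) -> np.ndarray:
        ids = cohorts[role]["participant_id"]
        return np.stack([volumes[sid][channel:channel + 1] for sid in ids])

    # ---- per-modality models -------------------------------------------
    pred_tables, ba_rows, calib_rows = [], [], []
    morph_stats_all, sens_stats_all = [], []
    roi_matrices: dict[tuple[str, str], object] = {}
    model_meta = {}
    for c in range(config.n_channels):
        modality = f"chan-{c}"
        spec = NetSpec(input_shape=tuple(config.grid_shape), in_channels=1,
                       encoder_widths=tuple(config.encoder_widths),
                       latent_dim=config.latent_dim,
                       head_widths=tuple(config.head_widths))

        status["stage"] = f"train-cae[{modality}]"
        x_pre = stack_for("pretrain", c)
        n_val = max(1, int(round(config.cae_val_fraction * len(x_pre))))
        order = np.random.default_rng(
            _subseed(seed, f"caesplit:{c}")).permutation(len(x_pre))
        x_val, x_tr = x_pre[order[:n_val]], x_pre[order[n_val:]]
        cae_cfg = TrainConfig(epochs=config.cae_epochs,
                              batch_size=config.batch_size,
                              learning_rate=config.cae_learning_rate,
                              selection_window=config.cae_selection_window,
                              seed=_subseed(seed, f"cae:{c}"))
        cae_store, cae_log = train_cae(x_tr, x_val, spec, cae_cfg)
        cae_state, cae_epoch = select_best_checkpoint(
            cae_store, config.cae_selection_window)
        log(f"[{status['stage']}] chose epoch {cae_epoch} "
            f"(val MSE {cae_store.scores[cae_epoch - 1]:.5f})")

        status["stage"] = f"train-regressor[{modality}]"
        model = transfer_encoder(cae_state, spec,
                                 seed=_subseed(seed, f"head:{c}"))
        reg_cfg = TrainConfig(epochs=config.reg_epochs,
                              batch_size=config.batch_size,
                              learning_rate=config.reg_learning_rate,
                              selection_window=config.reg_selection_window,
                              seed=_subseed(seed, f"reg:{c}"))
        reg_store, reg_log = train_regressor(
            model, stack_for("train", c), cohorts["train"]["age"].to_numpy(),
            stack_for("select", c), cohorts["select"]["age"].to_numpy(),
            spec, reg_cfg)
        best_state, reg_epoch = select_best_checkpoint(
            reg_store, config.reg_selection_window)
        model.load_state_dict(best_state)
        val_mae = reg_store.scores[reg_epoch - 1]
        log(f"[{status['stage']}] chose epoch {reg_epoch} (val MAE {val_mae:.2f} y)")

        status["stage"] = f"bias-correction[{modality}]"
        corr_cohort = cohorts["correct"]
        corr_pred = predict_age(model, stack_for("correct", c))
        bias = fit_bias_correction(corr_pred - corr_cohort["age"].to_numpy(),
                                   corr_cohort["age"].to_numpy(),
                                   fit_set_id="correct")

        status["stage"] = f"predict-clinical[{modality}]"
        clin_cohort = cohorts["clinical"]
        clin_pred = predict_age(model, stack_for("clinical", c))
        table = apply_bias_correction(
            build_prediction_table(clin_cohort, clin_pred), bias)
        table.insert(0, "modality", modality)
        pred_tables.append(table)

        status["stage"] = f"brainage-ancova[{modality}]"
        for corrected in (True, False):
            res = ancova_brainage(table, covariates=config.brainage_covariates,
                                  corrected=corrected)
            res.insert(0, "modality", modality)
            ba_rows.append(res)

        status["stage"] = f"calibrate-noise[{modality}]"
        calib_cohort = corr_cohort.iloc[:config.calib_max_subjects]
        calib_vols = [volumes[sid][c:c + 1]
                      for sid in calib_cohort["participant_id"]]
        report = calibrate_noise(
            model, calib_vols, calib_cohort["age"].to_numpy(), atlas,
            grid=default_noise_grid(),
            cfg=SaliencyConfig(n_samples=config.calib_n_samples,
                               seed=_subseed(seed, f"calib:{c}")))
        log(f"[{status['stage']}] chose noise level {report.chosen_level:.2f} "
            f"(mean |r| {report.scores[report.chosen_level]:.3f})")
        for level, score in report.scores.items():
            calib_rows.append({"modality": modality, "level": level,
                               "mean_abs_r": score,
                               "chosen": level == report.chosen_level})

        status["stage"] = f"saliency[{modality}]"
        sal_maps = {}
        for i, sid in enumerate(clin_cohort["participant_id"]):
            cfg_s = SaliencyConfig(noise_level=report.chosen_level,
                                   n_samples=config.saliency_n_samples,
                                   seed=_subseed(seed, f"sal:{c}:{sid}"),
                                   sigma_reference=report.sigma_reference)
            smap = smoothgrad(model, volumes[sid][c:c + 1], cfg_s)[0]
            sal_maps[sid] = smap
            if config.write_volumes:
                save_nifti(out / "dataset" / sid / f"chan-{c}_saliency.nii.gz",
                           smap)

        status["stage"] = f"roi-stats[{modality}]"
        morph_vols = {sid: volumes[sid][c]
                      for sid in clin_cohort["participant_id"]}
        morph_mat = build_roi_matrix(morph_vols, atlas, labels=labels,
                                     map_type="morphometric", modality=modality)
        sens_mat = build_roi_matrix(sal_maps, atlas, labels=labels,
                                    map_type="sensitivity", modality=modality)
        morph_mat.values.to_csv(out / f"roi_matrix_morph_{modality}.csv")
        sens_mat.values.to_csv(out / f"roi_matrix_sens_{modality}.csv")
        roi_matrices[("morphometric", modality)] = morph_mat
        roi_matrices[("sensitivity", modality)] = sens_mat
        morph_stats_all.append(roi_ancova(morph_mat, clin_cohort,
                                          covariates=config.roi_covariates,
                                          alpha=config.alpha))
        sens_stats_all.append(roi_ancova(sens_mat, clin_cohort,
                                         covariates=config.roi_covariates,
                                         alpha=config.alpha))
        model_meta[modality] = {
            "cae_epoch": int(cae_epoch), "reg_epoch": int(reg_epoch),
            "val_mae": float(val_mae),
            "noise_level": float(report.chosen_level),
            "sigma_reference": float(report.sigma_reference),
            "bias_alpha": bias.alpha, "bias_beta": bias.beta,
        }
        save_model(out / "models" / f"regressor_{modality}",
                   model.state_dict(),
                   {"spec": asdict(spec), "modality": modality,
                    **model_meta[modality]})

    # ---- tables and stage-2 concordance --------------------------------
    status["stage"] = "write-tables"
    predictions = pd.concat(pred_tables, ignore_index=True)
    brainage_ancova_df = pd.concat(ba_rows, ignore_index=True)
    noise_calibration = pd.DataFrame(calib_rows)
    morph_stats = pd.concat(morph_stats_all, ignore_index=True)
    sens_stats = pd.concat(sens_stats_all, ignore_index=True)

    predictions.to_csv(out / "predictions.csv", index=False)
    brainage_ancova_df.to_csv(out / "brainage_ancova.csv", index=False)
    noise_calibration.to_csv(out / "noise_calibration.csv", index=False)
    for name, df in (("morph", morph_stats), ("sens", sens_stats)):
        for factor in ("age", "condition"):
            df[df["factor"] == factor].to_csv(
                out / f"roi_stats_{name}_{factor}.csv", index=False)

    status["stage"] = "concordance"
    concord = concordance_report(morph_stats, sens_stats,
                                 factors=("age", "condition"))
    concord.to_csv(out / "concordance.csv", index=False)

    status["stage"] = "manifest"
    csvs = sorted(out.glob("*.csv"))
    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            str(sorted(config.to_dict().items())).encode()).hexdigest(),
        "software": {"python": sys.version.split()[0],
                     "xbrainage": __version__,
                     "numpy": np.__version__, "pandas": pd.__version__},
        "models": model_meta,
        "outputs": {p.name: _digest(p) for p in csvs},
        "ground_truth_disease_regions": list(effects.disease_set),
    }
    write_json(out / "manifest.json", manifest)

    return {
        "out_dir": out,
        "config": config,
        "atlas": atlas,
        "region_table": region_table,
        "effects": effects,
        "cohorts": cohorts,
        "predictions": predictions,
        "brainage_ancova": brainage_ancova_df,
        "noise_calibration": noise_calibration,
        "roi_stats_morph": morph_stats,
        "roi_stats_sens": sens_stats,
        "roi_matrices": roi_matrices,
        "concordance": concord,
        "model_meta": model_meta,
        "manifest": manifest,
    }


def rerun_concordance(out_dir: str | Path) -> pd.DataFrame:
    """Recompute stage 2 alone from the persisted stage-1 tables."""
    out = Path(out_dir)
    morph = pd.concat([pd.read_csv(out / f"roi_stats_morph_{f}.csv")
                       for f in ("age", "condition")], ignore_index=True)
    sens = pd.concat([pd.read_csv(out / f"roi_stats_sens_{f}.csv")
                      for f in ("age", "condition")], ignore_index=True)
    concord = concordance_report(morph, sens, factors=("age", "condition"))
    concord.to_csv(out / "concordance.csv", index=False)
    return concord
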