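"""End-to-end workflow: simulate → augment → preprocess → train → evaluate →
rank → physics, with validated configuration, derived per-stage seeds, and a
run manifest.

Desk-scale defaults (2,000 augmented records, 10×50 boosting stages, 10 MCCV
iterations) run the full loop in minutes on one CPU; the study-scale numbers
(17,800 records, 1,000×500 stages, 100 iterations) are one config switch away.
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import boost, cohort, evaluate, gan, ranking
from .data import (
    FormulationDataset,
    FormulationError,
    balance_by_undersampling,
    remove_outliers,
    split_dataset,
    write_csv,
)
from .physics import MembraneParams, energy_radius_sweep, equilibrium_radius

STAGES = ("simulate", "augment", "preprocess", "train", "evaluate", "rank", "physics")


class ConfigError(FormulationError):
    pass


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CohortSection(_Section):
    n_experimental: int = Field(225, ge=10)
    dirichlet_mean: tuple[float, float, float, float, float] = (0.46, 0.12, 0.18, 0.14, 0.10)
    dirichlet_concentration: float = Field(60.0, gt=0)
    noise_sd: tuple[float, float, float] = (2.0, 0.01, 1.0)


class GanSection(_Section):
    latent_dim: int = Field(8, ge=1)
    hidden: tuple[int, ...] = (64, 64)
    epochs: int = Field(4000, ge=1)
    batch_size: int = Field(32, ge=1)
    lr_g: float = Field(1e-3, gt=0)
    lr_d: float = Field(1e-3, gt=0)
    n_augmented: int = Field(2000, ge=100)  # study scale: 17800


class PreprocessSection(_Section):
    outlier_k: float = Field(3.5, gt=0)
    balance: bool = True
    balance_bins: int = Field(10, ge=2)
    balance_on: Literal["size_nm", "pdi", "zeta_mv"] = "size_nm"
    train_frac: float = Field(0.7, gt=0, lt=1)
    stratify_on: Optional[Literal["size_nm", "pdi", "zeta_mv"]] = "size_nm"


class BoostSection(_Section):
    leaf_size: int = Field(8, ge=1)
    learning_rate: float = Field(0.02, gt=0, le=1)
    epochs: int = Field(10, ge=1)  # study scale: 1000
    iterations_per_epoch: int = Field(50, ge=1)  # study scale: 500
    weight_mode: Literal["inverted", "as_printed", "uniform"] = "inverted"


class EvalSection(_Section):
    mccv_iterations: int = Field(10, ge=1)
    run_mccv: bool = False
    run_ablation: bool = False


class RankingSection(_Section):
    k: int = Field(10, ge=1)
    standardize: bool = True
    profiles: bool = True


class PhysicsSection(_Section):
    kappa: float = Field(20.0, gt=0)
    kappa_bar: float = -15.0
    c0: float = 2.0 / 60.0
    gamma: float = 10.0
    temperature: float = Field(310.0, gt=0)
    entropy_s: float = 1.0
    r_sat: float = Field(20.0, gt=0)
    r_min: float = Field(10.0, gt=0)
    r_max: float = 300.0


class PipelineConfig(_Section):
    seed: int = 0
    outdir: str = "runs/default"
    cohort: CohortSection = Field(default_factory=CohortSection)
    gan: GanSection = Field(default_factory=GanSection)
    preprocess: PreprocessSection = Field(default_factory=PreprocessSection)
    boost: BoostSection = Field(default_factory=BoostSection)
    eval: EvalSection = Field(default_factory=EvalSection)
    ranking: RankingSection = Field(default_factory=RankingSection)
    physics: PhysicsSection = Field(default_factory=PhysicsSection)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        idx = STAGES.index(stage)
        ss = np.random.SeedSequence([self.seed, idx])
        return int(ss.generate_state(1)[0] % (2**31 - 1))


def validate_config(path) -> PipelineConfig:
    """Load and fully validate a YAML pipeline config."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return PipelineConfig(**raw)
    except ValidationError as exc:
        lines = [
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        ]
        raise ConfigError("invalid pipeline config:\n  " + "\n  ".join(lines)) from exc


def _cohort_config(cfg: PipelineConfig) -> cohort.CohortConfig:
    return cohort.CohortConfig(
        n_experimental=cfg.cohort.n_experimental,
        dirichlet_mean=cfg.cohort.dirichlet_mean,
        dirichlet_concentration=cfg.cohort.dirichlet_concentration,
        noise_sd=cfg.cohort.noise_sd,
        seed=cfg.stage_seed("simulate"),
    )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages, write artifacts + manifest, return the manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": json.loads(cfg.model_dump_json()),
        "stages": [],
        "files": [],
        "seeds": {s: cfg.stage_seed(s) for s in STAGES},
    }

    def emit(name: str, frame_writer) -> None:
        path = outdir / name
        frame_writer(path)
        manifest["files"].append(name)

    def finish_stage(name: str, t0: float, **info) -> None:
        manifest["stages"].append(
            {"name": name, "seconds": round(time.time() - t0, 3), **info}
        )

    current = "simulate"
    try:
        # 1. simulate ---------------------------------------------------------
        t0 = time.time()
        ccfg = _cohort_config(cfg)
        experimental = cohort.make_experimental_set(ccfg)
        emit("cohort.csv", lambda p: write_csv(experimental, p))
        finish_stage("simulate", t0, n_records=len(experimental))

        # 2. augment ----------------------------------------------------------
        current = "augment"
        t0 = time.time()
        gan_seed = cfg.stage_seed("augment")
        gcfg = gan.GANConfig(
            latent_dim=cfg.gan.latent_dim,
            hidden=cfg.gan.hidden,
            epochs=cfg.gan.epochs,
            batch_size=cfg.gan.batch_size,
            lr_g=cfg.gan.lr_g,
            lr_d=cfg.gan.lr_d,
            seed=gan_seed,
        )
        state = gan.train_gan(experimental, gcfg)
        emit("lipidgan_state.json", state.to_json)
        comps = gan.generate_formulations(state, cfg.gan.n_augmented, seed=gan_seed + 1)
        augmented = cohort.label_with_truth(
            comps, ccfg, with_noise=True, seed=gan_seed + 2, provenance="gan_synthetic"
        )
        fidelity = gan.fidelity_report(experimental, FormulationDataset.from_arrays(comps))
        emit("augmented.csv", lambda p: write_csv(augmented, p))
        finish_stage(
            "augment",
            t0,
            n_generated=len(augmented),
            fidelity_r=fidelity.pooled_quantile_r,
            fidelity_mae=fidelity.mean_mae,
        )

        # 3. preprocess ---------------------------------------------------------
        current = "preprocess"
        t0 = time.time()
        pre = remove_outliers(augmented, k=cfg.preprocess.outlier_k)
        if cfg.preprocess.balance:
            pre = balance_by_undersampling(
                pre,
                n_bins=cfg.preprocess.balance_bins,
                target_cqa=cfg.preprocess.balance_on,
                seed=cfg.stage_seed("preprocess"),
            )
        train, blind = split_dataset(
            pre,
            cfg.preprocess.train_frac,
            seed=cfg.stage_seed("preprocess"),
            stratify_on=cfg.preprocess.stratify_on,
        )
        emit("train.csv", lambda p: write_csv(train, p))
        emit("blind.csv", lambda p: write_csv(blind, p))
        finish_stage(
            "preprocess", t0, n_after_outliers_and_balance=len(pre),
            n_train=len(train), n_blind=len(blind),
        )

        # 4. train ------------------------------------------------------------
        current = "train"
        t0 = time.time()
        bcfg = boost.BoostConfig(
            leaf_size=cfg.boost.leaf_size,
            learning_rate=cfg.boost.learning_rate,
            epochs=cfg.boost.epochs,
            iterations_per_epoch=cfg.boost.iterations_per_epoch,
            weight_mode=cfg.boost.weight_mode,
            seed=cfg.stage_seed("train"),
        )
        model = boost.EnsembleModel(bcfg).fit(train)
        emit("model.json", model.save)
        finish_stage("train", t0, stages_per_cqa=bcfg.epochs * bcfg.iterations_per_epoch)

        # 5. evaluate -----------------------------------------------------------
        current = "evaluate"
        t0 = time.time()
        obs = blind.cqas()
        pred = model.predict(blind.compositions())
        report = evaluate.metrics_report(obs, pred)
        metrics_payload = {
            name: {k: (None if isinstance(v, float) and np.isnan(v) else v)
                   for k, v in vars(m).items() if k != "residuals"}
            for name, m in report.items()
        }
        emit("metrics.json", lambda p: Path(p).write_text(json.dumps(metrics_payload, indent=2)))

        spread = model.stage_prediction_spread(blind.compositions())
        roc_payload = {}
        for j, name in enumerate(("size_nm", "pdi", "zeta_mv")):
            fpr, tpr, auc_val = evaluate.roc_accuracy(obs[:, j], pred[:, j], -spread[:, j])
            roc_payload[name] = auc_val
            frame = pd.DataFrame({"fpr": fpr, "tpr": tpr})
            emit(f"roc_{name}.csv", lambda p, f=frame: f.to_csv(p, index=False))
        emit("roc_auc.json", lambda p: Path(p).write_text(json.dumps(roc_payload, indent=2)))

        resid = {
            name: evaluate.residual_analysis(obs[:, j], pred[:, j])
            for j, name in enumerate(("size_nm", "pdi", "zeta_mv"))
        }
        resid_payload = {
            k: {"mean": r.mean, "skewness": r.skewness,
                "sign_test_p": r.sign_test_p, "unbiased": bool(r.unbiased)}
            for k, r in resid.items()
        }
        emit("residuals.json", lambda p: Path(p).write_text(json.dumps(resid_payload, indent=2)))

        blind_rmse = np.sqrt(np.mean((pred - obs) ** 2, axis=0))
        corr = ranking.cma_cqa_correlation(
            blind.compositions(), obs, mode="rmse_normalized", blind_rmse=blind_rmse
        )
        emit("correlation_matrix.csv", lambda p: corr.values.to_csv(p))

        extra: dict = {}
        if cfg.eval.run_mccv:
            mccv_rep = evaluate.mccv(
                pre,
                lambda: boost.EnsembleModel(bcfg),
                iterations=cfg.eval.mccv_iterations,
                train_frac=cfg.preprocess.train_frac,
                seed=cfg.stage_seed("evaluate"),
                stratify_on=cfg.preprocess.stratify_on,
            )
            emit("mccv_rmse.csv", lambda p: mccv_rep.rmse.to_csv(p, index=False))
            emit("mccv_eq10.csv", lambda p: mccv_rep.eq10.to_csv(p, index=False))
            extra["epsilon_mccv"] = mccv_rep.epsilon_mean
        if cfg.eval.run_ablation:
            table = evaluate.ablation(
                pre,
                lambda: boost.EnsembleModel(bcfg),
                seed=cfg.stage_seed("evaluate"),
                train_frac=cfg.preprocess.train_frac,
                stratify_on=cfg.preprocess.stratify_on,
            )
            emit("ablation.csv", lambda p: table.to_csv(p, index=False))
        finish_stage("evaluate", t0, auc=roc_payload, **extra)

        # 6. rank --------------------------------------------------------------
        current = "rank"
        t0 = time.time()
        cands = ranking.select_top_candidates(
            obs, pred, blind.compositions(), k=cfg.ranking.k,
            standardize=cfg.ranking.standardize,
        )
        cands = ranking.rerank_by_loss_weights(cands, model)
        emit("ranked_candidates.csv",
             lambda p: ranking.candidates_frame(cands).to_csv(p, index=False))
        if cfg.ranking.profiles:
            for name, profile in ranking.DEFAULT_PROFILES.items():
                pc = ranking.rank_for_profile(
                    obs, pred, blind.compositions(), profile, k=cfg.ranking.k
                )
                emit(f"ranked_{name}.csv",
                     lambda p, c=pc: ranking.candidates_frame(c).to_csv(p, index=False))
        finish_stage("rank", t0, k=cfg.ranking.k)

        # 7. physics -------------------------------------------------------------
        current = "physics"
        t0 = time.time()
        params = MembraneParams(
            kappa=cfg.physics.kappa, kappa_bar=cfg.physics.kappa_bar,
            c0=cfg.physics.c0, gamma=cfg.physics.gamma,
            temperature=cfg.physics.temperature, entropy_s=cfg.physics.entropy_s,
            r_sat=cfg.physics.r_sat,
        )
        eq = equilibrium_radius(params, cfg.physics.r_min, cfg.physics.r_max)
        sweep = energy_radius_sweep(params, cfg.physics.r_min, cfg.physics.r_max)
        emit("energy_sweep.csv", lambda p: sweep.to_csv(p, index=False))
        emit("equilibrium.json", lambda p: Path(p).write_text(json.dumps(
            {"radius_nm": eq.radius_nm, "diameter_nm": eq.diameter_nm,
             "gibbs_kt": eq.gibbs, "at_boundary": eq.at_boundary}, indent=2)))
        finish_stage("physics", t0, equilibrium_diameter_nm=eq.diameter_nm)

    except Exception as exc:
        manifest["failed_stage"] = current
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
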