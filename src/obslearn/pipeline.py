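"""End-to-end pipeline: simulate -> fit -> compare -> recover -> metrics ->
regressions -> posterior predictive checks, with a content-hashed manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import recovery as rec
from .config import RunConfig
from .hier_fit import fit_hierarchical
from .obs_models import MODEL_KINDS
from .partner_metrics import fit_practice_individual, partner_metrics_table, selection_regressors
from .ppc import run_ppc
from .regressions import SELECTION_TERMS, build_selection_design, fit_mixed_logistic, optionwise_glmm
from .synthetic_data import generate_study
from .task_core import write_dataset

logger = logging.getLogger("obslearn.pipeline")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _effects_frame(analysis: str, effects) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "analysis": analysis, "term": e.term, "estimate": e.estimate, "se": e.se,
                "stat": e.stat, "df": e.df, "p": e.p, "pooled": e.pooled, "engine": e.engine,
            }
            for e in effects
        ]
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the artifact manifest (name -> path, sha256).

    Any stage failure propagates with the stage name attached.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    manifest: dict[str, dict] = {}
    stage = "init"

    def emit(name: str, path: Path):
        manifest[name] = {"path": str(path), "sha256": _sha256(path)}

    try:
        t0 = time.time()
        stage = "simulate"
        design = config.design.to_design(config.seed)
        dataset, truth = generate_study(design, config.model)
        write_dataset(dataset, out / "study.csv")
        truth.write(out / "truth.csv")
        emit("study", out / "study.csv")
        emit("truth", out / "truth.csv")
        logger.info("simulate done (%.1fs)", time.time() - t0)

        stage = "fit"
        fits = {}
        waic_rows = []
        for i, kind in enumerate(MODEL_KINDS):
            fits[kind] = fit_hierarchical(
                dataset, kind, chains=config.fit.chains, warmup=config.fit.warmup,
                draws=config.fit.draws, seed=config.seed + 101 + i,
            )
            fits[kind].save(out / f"fit_{kind}.npz")
            emit(f"fit_{kind}", out / f"fit_{kind}.npz")
            w = fits[kind].waic
            waic_rows.append({"model": kind, "waic": w.waic, "lppd": w.lppd, "p_waic": w.p_waic,
                              "max_rhat": fits[kind].diagnostics["max_rhat"]})
        pd.DataFrame(waic_rows).to_csv(out / "waic.csv", index=False)
        emit("waic", out / "waic.csv")
        logger.info("fit + waic done")

        stage = "recovery"
        rdesign = rec.REDUCED_DESIGN if config.recovery.reduced_scale else design
        rfit = rec.REDUCED_FIT if config.recovery.reduced_scale else rec.FitSettings(
            config.fit.chains, config.fit.warmup, config.fit.draws
        )
        cm = rec.model_recovery(rdesign, config.recovery.n_reps, rfit, seed=config.seed + 211)
        cm.table.to_csv(out / "model_recovery.csv")
        emit("model_recovery", out / "model_recovery.csv")
        pr = rec.parameter_recovery(rdesign, config.recovery.n_reps, rfit, seed=config.seed + 223)
        pr.correlations.to_csv(out / "parameter_recovery.csv", index=False)
        emit("parameter_recovery", out / "parameter_recovery.csv")
        rec.stratified_recovery(pr).to_csv(out / "stratified_recovery.csv", index=False)
        emit("stratified_recovery", out / "stratified_recovery.csv")
        logger.info("recovery done")

        stage = "metrics"
        indiv = fit_practice_individual(
            dataset, chains=config.fit.chains, warmup=config.fit.warmup,
            draws=config.fit.draws, seed=config.seed + 307,
        )
        indiv.save(out / "fit_practice.npz")
        emit("fit_practice", out / "fit_practice.npz")
        metrics = partner_metrics_table(dataset, indiv)
        metrics.to_csv(out / "metrics.csv", index=False)
        emit("metrics", out / "metrics.csv")
        regressors = selection_regressors(metrics)
        logger.info("metrics done")

        stage = "regressions"
        frames = []
        for which in ("model1", "model2", "factors"):
            design_frame = build_selection_design(dataset, which, metrics=regressors if which == "factors" else None)
            fit = fit_mixed_logistic(design_frame, "Y", SELECTION_TERMS[which], engine=config.regress.engine)
            frames.append(_effects_frame(f"selection_{which}", fit.effects))
        for moderator, label in (("P", "style_between"), ("D", "style_within")):
            try:
                ow = optionwise_glmm(dataset, moderator, engine=config.regress.engine)
                frames.append(_effects_frame(label, ow.pooled))
            except ValueError as exc:
                logger.warning("%s skipped: %s", label, exc)
        pd.concat(frames).to_csv(out / "regressions.csv", index=False)
        emit("regressions", out / "regressions.csv")
        logger.info("regressions done")

        stage = "ppc"
        ppc = run_ppc(
            fits["full"], dataset, n_reps=config.ppc.n_reps, seed=config.seed + 401,
            refit_glmm=config.ppc.refit_glmm, glmm_engine=config.ppc.glmm_engine,
        )
        ppc_frame = pd.DataFrame({"trial": range(len(ppc.curve_mean)),
                                  "curve_mean": ppc.curve_mean, "curve_sd": ppc.curve_sd})
        ppc_frame.to_csv(out / "ppc_curve.csv", index=False)
        emit("ppc_curve", out / "ppc_curve.csv")
        if ppc.glmm_effects is not None:
            ppc.glmm_effects.describe().to_csv(out / "ppc_effects.csv")
            emit("ppc_effects", out / "ppc_effects.csv")
        logger.info("ppc done; total %.1fs", time.time() - t0)

        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
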