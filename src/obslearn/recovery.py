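"""Model-recovery and parameter-recovery studies.

Model recovery: generate synthetic studies from each candidate model, fit
all three models to each, and tabulate which model wins by WAIC — a
confusion matrix whose rows (generating model) should concentrate on the
diagonal (best-fitting model) if the comparison is identifiable.

Parameter recovery: generate from the full model, refit it, and correlate
posterior-mean parameter estimates with the generating values across
participants, optionally stratified by the participants' partner-noise
preference (high-noise group: more than half of blocks with a high-noise
partner; low-noise group: more than half low-noise; equal splits are
discarded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hier_fit import fit_hierarchical
from .obs_models import MODEL_KINDS
from .synthetic_data import GroundTruth, StudyDesign, generate_study

logger = logging.getLogger(__name__)

FULL_PARAMS = ("alpha_v", "alpha_a", "w_a", "beta")


@dataclass(frozen=True)
class FitSettings:
    """MCMC settings shared by the recovery loops."""

    chains: int = 4
    warmup: int = 1000
    draws: int = 1000


#: Reduced-scale settings for quick validation runs.
REDUCED_FIT = FitSettings(chains=4, warmup=200, draws=200)
REDUCED_DESIGN = StudyDesign(n_participants=10, n_blocks=2)


@dataclass
class ConfusionMatrix:
    """Proportion of replicates each generating model (row) was won by each
    fitted model (column) under WAIC."""

    table: pd.DataFrame  # index: generating model, columns: best-fitting model
    n_failed: int = 0

    def diagonal_is_row_max(self) -> bool:
        t = self.table
        return all(t.loc[k, k] >= t.loc[k].max() for k in t.index)


@dataclass
class RecoveryResult:
    """Per-replicate recovery correlations and per-participant signed errors."""

    correlations: pd.DataFrame  # columns: rep + one column per parameter
    errors: pd.DataFrame  # participant_id, rep, parameter, true, estimated, error, group


def _rep_seed(master: int, *key: int) -> int:
    """Deterministic per-replicate seed derived from the master seed."""
    return int(np.random.SeedSequence(master, spawn_key=key).generate_state(1)[0] % (2**31))


def model_recovery(
    design: StudyDesign,
    n_reps: int = 40,
    fit: FitSettings = FitSettings(),
    seed: int = 0,
) -> ConfusionMatrix:
    """Confusion matrix over ``n_reps`` replicates per generating model."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    counts = pd.DataFrame(0.0, index=list(MODEL_KINDS), columns=list(MODEL_KINDS))
    n_failed = 0
    for g, gen_kind in enumerate(MODEL_KINDS):
        valid = 0
        for rep in range(n_reps):
            rep_seed = _rep_seed(seed, g, rep)
            dataset, _ = generate_study(design, gen_kind, seed=rep_seed)
            try:
                waics = {
                    kind: fit_hierarchical(
                        dataset, kind, chains=fit.chains, warmup=fit.warmup, draws=fit.draws,
                        seed=rep_seed + 1,
                    ).waic.waic
                    for kind in MODEL_KINDS
                }
            except Exception as exc:  # pragma: no cover - defensive
                n_failed += 1
                logger.warning("model_recovery: fit failed (gen=%s rep=%d): %s", gen_kind, rep, exc)
                continue
            winner = min(waics, key=waics.get)
            counts.loc[gen_kind, winner] += 1
            valid += 1
        if valid:
            counts.loc[gen_kind] /= valid
    return ConfusionMatrix(table=counts, n_failed=n_failed)


def parameter_recovery(
    design: StudyDesign,
    n_reps: int = 40,
    fit: FitSettings = FitSettings(),
    seed: int = 0,
    params_fn=None,
) -> RecoveryResult:
    """Full-model parameter recovery over ``n_reps`` replicates.

    ``params_fn(i, rng) -> LearnerParams``, if given, replaces the default
    Beta/Uniform generative draws (used for high-identifiability designs in
    validation).
    """
    corr_rows = []
    err_rows = []
    for rep in range(n_reps):
        rep_seed = _rep_seed(seed, rep)
        dataset, truth = generate_study(design, "full", seed=rep_seed, params_fn=params_fn)
        result = fit_hierarchical(
            dataset, "full", chains=fit.chains, warmup=fit.warmup, draws=fit.draws, seed=rep_seed + 1
        )
        est = result.participant_means
        tru = truth.params.set_index("participant_id")
        groups = classify_preference(truth)
        row = {"rep": rep}
        for p in FULL_PARAMS:
            row[p] = float(np.corrcoef(tru[p], est.loc[tru.index, p])[0, 1])
            for pid in tru.index:
                err_rows.append(
                    {
                        "participant_id": pid,
                        "rep": rep,
                        "parameter": p,
                        "true": float(tru.loc[pid, p]),
                        "estimated": float(est.loc[pid, p]),
                        "error": float(est.loc[pid, p] - tru.loc[pid, p]),
                        "group": groups.get(pid),
                    }
                )
        corr_rows.append(row)
    return RecoveryResult(correlations=pd.DataFrame(corr_rows), errors=pd.DataFrame(err_rows))


def classify_preference(truth: GroundTruth) -> dict[str, str | None]:
    """Partner-noise preference per participant from block conditions.

    More than half of blocks high-noise: 'high'; more than half low-noise:
    'low'; an exact split: None (discarded from stratified summaries).
    """
    out: dict[str, str | None] = {}
    for pid, g in truth.blocks.groupby("participant_id"):
        n_high = int((g["partner_noise"] == "high").sum())
        n_low = int((g["partner_noise"] == "low").sum())
        out[str(pid)] = "high" if n_high > n_low else ("low" if n_low > n_high else None)
    return out


def stratified_recovery(result: RecoveryResult, min_group: int = 3) -> pd.DataFrame:
    """Per-group recovery summary: correlation and mean signed error.

    Groups with fewer than ``min_group`` participants in a replicate get NaN
    correlations with a logged warning.
    """
    rows = []
    for (rep, group, param), g in result.errors.dropna(subset=["group"]).groupby(
        ["rep", "group", "parameter"]
    ):
        if len(g) < min_group:
            logger.warning(
                "stratified_recovery: rep %s group %r has %d participants (<%d); correlation omitted",
                rep, group, len(g), min_group,
            )
            r = float("nan")
        else:
            r = float(np.corrcoef(g["true"], g["estimated"])[0, 1])
        rows.append(
            {
                "rep": rep,
                "group": group,
                "parameter": param,
                "n": len(g),
                "correlation": r,
                "mean_error": float(g["error"].mean()),
            }
        )
    return pd.DataFrame(rows)
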