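"""Posterior predictive checks for the full model.

From a fitted hierarchical model, regenerate the study repeatedly with each
participant's estimated parameters under the same conditions (block count,
trial counts, partner noise levels), then recompute the learning curve and
the between-participant learning-style GLMM on each simulated dataset.
Across-replicate means and standard deviations summarize what behavior the
fitted model reproduces.

Partner event streams are regenerated per replicate from the recorded
partner noise condition (same conditions, fresh realizations).  Participant
parameters are posterior means by default; optionally one joint posterior
draw per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agents import QAgentParams, simulate_partner
from .hier_fit import FitResult, to_natural
from .obs_models import LearnerParams, simulate_learner
from .regressions import EffectEstimate, optionwise_glmm
from .synthetic_data import _participant_rng  # deterministic per-replicate streams
from .task_core import (
    BlockRecord,
    ParticipantRecord,
    RewardStructure,
    StudyDataset,
    learning_curve,
)


@dataclass
class PPCResult:
    curves: np.ndarray  # (n_reps, n_trials) per-replicate learning curves
    curve_mean: np.ndarray
    curve_sd: np.ndarray  # across-replicate SD (NaN when n_reps == 1, flagged)
    glmm_effects: pd.DataFrame | None  # per-replicate pooled fixed effects
    effect_mean: pd.Series | None
    effect_sd: pd.Series | None
    warnings: list[str]


def _params_for(fit: FitResult, pid: str, draw: tuple[int, int] | None) -> LearnerParams:
    if draw is None:
        row = fit.participant_means.loc[pid]
        return LearnerParams(
            alpha_v=float(row.get("alpha_v", 0.0)),
            alpha_a=float(row.get("alpha_a", 0.0)),
            w_a=float(row.get("w_a", 0.0)),
            beta=float(row["beta"]),
        )
    c, d = draw
    i = fit.participant_ids.index(pid)
    vals = {}
    for j, name in enumerate(fit.param_names):
        transform = "exp" if name == "beta" else "logistic"
        vals[name] = float(to_natural(fit.theta_raw[c, d, i, j], transform))
    return LearnerParams(
        alpha_v=vals.get("alpha_v", 0.0), alpha_a=vals.get("alpha_a", 0.0),
        w_a=vals.get("w_a", 0.0), beta=vals["beta"],
    )


def simulate_from_fit(
    fit: FitResult,
    dataset: StudyDataset,
    rng: np.random.Generator,
    draw: tuple[int, int] | None = None,
    structure: RewardStructure | None = None,
) -> StudyDataset:
    """One simulated study under the empirical conditions of ``dataset``.

    For each participant and block, a fresh partner stream is generated from
    the block's recorded noise condition and the participant's choices are
    simulated from their fitted parameters (model kind = the fitted model).
    """
    structure = structure or RewardStructure()
    kind = fit.model_name
    sims = []
    for p in dataset.participants:
        params = _params_for(fit, p.participant_id, draw)
        blocks = []
        for b in p.blocks:
            partner = QAgentParams.preset(f"{b.selected_partner}_noise")
            trials = simulate_partner(
                partner, structure, len(b.observational_trials), rng,
                phase="observational", block_id=b.block_id,
            )
            pc = np.array([t.partner_choice for t in trials])
            pr = np.array([t.partner_reward for t in trials])
            cc = simulate_learner(params, kind, pc, pr, rng)
            obs = tuple(
                t.__class__(
                    block_id=b.block_id, trial_index=i, phase="observational",
                    partner_choice=int(pc[i]), partner_reward=int(pr[i]), participant_choice=int(cc[i]),
                )
                for i, t in enumerate(trials)
            )
            blocks.append(BlockRecord(b.block_id, b.passive, b.selected_partner, obs))
        sims.append(ParticipantRecord(p.participant_id, p.practice_individual, p.practice_observational, tuple(blocks)))
    return StudyDataset(sims)


def run_ppc(
    fit: FitResult,
    dataset: StudyDataset,
    n_reps: int = 500,
    seed: int = 0,
    refit_glmm: bool = True,
    glmm_engine: str = "glm",
    draw_per_rep: bool = False,
    structure: RewardStructure | None = None,
) -> PPCResult:
    """Posterior predictive check: learning curves and GLMM effects across
    ``n_reps`` simulated studies."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    warnings_list = []
    if n_reps == 1:
        warnings_list.append("single replicate: across-replicate SDs undefined")
    curves = []
    effect_rows = []
    C, D = fit.theta_raw.shape[:2]
    for rep in range(n_reps):
        rng = _participant_rng(seed, rep)
        draw = None
        if draw_per_rep:
            draw = (int(rng.integers(C)), int(rng.integers(D)))
        sim = simulate_from_fit(fit, dataset, rng, draw=draw, structure=structure)
        curves.append(learning_curve(sim, structure))
        if refit_glmm:
            ow = optionwise_glmm(sim, "P", engine=glmm_engine)
            effect_rows.append({e.term: e.estimate for e in ow.pooled} | {"rep": rep})
    curves = np.asarray(curves)
    effects = pd.DataFrame(effect_rows).set_index("rep") if effect_rows else None
    return PPCResult(
        curves=curves,
        curve_mean=curves.mean(axis=0),
        curve_sd=curves.std(axis=0, ddof=1) if n_reps > 1 else np.full(curves.shape[1], np.nan),
        glmm_effects=effects,
        effect_mean=effects.mean() if effects is not None else None,
        effect_sd=effects.std(ddof=1) if effects is not None and n_reps > 1 else None,
        warnings=warnings_list,
    )
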