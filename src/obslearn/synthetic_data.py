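"""Synthetic study generator.

Emulates the full experimental protocol on simulated participants so every
downstream analysis runs without any external data: a 60-trial practice
individual-learning phase, a 60-trial practice observational phase with a
moderate-noise partner, then four main blocks, each with two 30-trial
passive demonstrations (one high-noise, one low-noise partner), an
exogenous partner selection (low-noise with probability 0.7, matching the
empirically observed selection distribution), and a 60-trial observational
phase with the selected partner.

Participant parameters are drawn from the generative distributions used in
the recovery analyses: Beta(1.1, 1.1) for the learning rates and the
imitation weight, Uniform(0, 30) for the inverse temperature.  Each
participant consumes an independent random stream spawned from the master
seed, so adding participants never perturbs earlier participants' data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .agents import QAgentParams, simulate_partner, softmax, Q_INIT
from .obs_models import LearnerParams, simulate_learner
from .task_core import (
    BlockRecord,
    N_OPTIONS,
    ParticipantRecord,
    PassivePhase,
    RewardStructure,
    StudyDataset,
    TrialRecord,
    sample_reward,
)


@dataclass(frozen=True)
class StudyDesign:
    """Structural constants of a study.

    Defaults reproduce the task protocol and the recovery-simulation
    conditions: 74 participants, 4 blocks, 30 passive trials per candidate
    partner, 60 observational trials, P(low-noise partner) = 0.7, reward
    probabilities (0.25, 0.50, 0.75), Beta(1.1, 1.1) rate/weight priors and
    U(0, 30) for the inverse temperature.
    """

    n_participants: int = 74
    n_blocks: int = 4
    passive_trials: int = 30
    observational_trials: int = 60
    practice_trials: int = 60
    p_low_noise: float = 0.7
    reward_probs: tuple[float, float, float] = (0.25, 0.50, 0.75)
    rate_prior: tuple[float, float] = (1.1, 1.1)
    beta_prior: tuple[float, float] = (0.0, 30.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_blocks", "passive_trials", "observational_trials", "practice_trials"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_participants < 0:
            raise ValueError("n_participants must be >= 0")
        if not (0.0 <= self.p_low_noise <= 1.0):
            raise ValueError("p_low_noise must be in [0, 1]")

    @property
    def structure(self) -> RewardStructure:
        return RewardStructure(self.reward_probs)


@dataclass
class GroundTruth:
    """Generating parameters and partner conditions aligned with a dataset."""

    params: pd.DataFrame  # participant_id, model_kind, alpha_v, alpha_a, w_a, beta
    blocks: pd.DataFrame  # participant_id, block_id, partner_noise

    def write(self, path: str | Path) -> None:
        wide = self.blocks.assign(key="block_" + self.blocks["block_id"].astype(str)).pivot(
            index="participant_id", columns="key", values="partner_noise"
        )
        self.params.set_index("participant_id").join(wide).reset_index().to_csv(path, index=False)


def draw_params(design: StudyDesign, rng: np.random.Generator) -> LearnerParams:
    """Draw one participant's generative parameters from the design priors."""
    a, b = design.rate_prior
    lo, hi = design.beta_prior
    return LearnerParams(
        alpha_v=float(rng.beta(a, b)),
        alpha_a=float(rng.beta(a, b)),
        w_a=float(rng.beta(a, b)),
        beta=float(rng.uniform(lo, hi)),
    )


def _participant_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _balanced_flags(n: int, rng: np.random.Generator) -> np.ndarray:
    """A shuffled half-true/half-false vector (counterbalancing across blocks)."""
    flags = np.zeros(n, dtype=bool)
    flags[: n // 2] = True
    rng.shuffle(flags)
    return flags


def _simulate_practice_individual(
    params: LearnerParams, design: StudyDesign, rng: np.random.Generator
) -> tuple[TrialRecord, ...]:
    """The participant plays the bandit alone with a Q-learning policy using
    their own reward-learning rate and inverse temperature."""
    q = np.full(N_OPTIONS, Q_INIT)
    structure = design.structure
    out = []
    for t in range(design.practice_trials):
        p = softmax(q, params.beta)
        choice = int(rng.choice(N_OPTIONS, p=p))
        reward = sample_reward(choice, structure, rng)
        q[choice] += params.alpha_v * (reward - q[choice])
        out.append(
            TrialRecord(
                block_id=0, trial_index=t, phase="practice_individual",
                partner_reward=reward, participant_choice=choice,
            )
        )
    return tuple(out)


def _observational_phase(
    params: LearnerParams,
    kind: str,
    partner: QAgentParams,
    design: StudyDesign,
    block_id: int,
    phase: str,
    n_trials: int,
    rng: np.random.Generator,
) -> tuple[TrialRecord, ...]:
    partner_trials = simulate_partner(partner, design.structure, n_trials, rng, phase=phase, block_id=block_id)
    pc = np.array([t.partner_choice for t in partner_trials])
    pr = np.array([t.partner_reward for t in partner_trials])
    cc = simulate_learner(params, kind, pc, pr, rng)
    return tuple(
        TrialRecord(
            block_id=block_id, trial_index=t, phase=phase,
            partner_choice=int(pc[t]), partner_reward=int(pr[t]), participant_choice=int(cc[t]),
        )
        for t in range(n_trials)
    )


def generate_participant(
    pid: str, params: LearnerParams, kind: str, design: StudyDesign, rng: np.random.Generator
) -> tuple[ParticipantRecord, list[str]]:
    """Simulate one participant; returns the record and per-block conditions."""
    practice_ind = _simulate_practice_individual(params, design, rng)
    practice_obs = _observational_phase(
        params, kind, QAgentParams.preset("practice"), design, 0, "practice_observational",
        design.practice_trials, rng,
    )
    conditions = np.where(rng.random(design.n_blocks) < design.p_low_noise, "low", "high")
    high_first = _balanced_flags(design.n_blocks, rng)
    high_left = _balanced_flags(design.n_blocks, rng)
    blocks = []
    for b in range(design.n_blocks):
        bid = b + 1
        phases = []
        order_of = {"high": 1 if high_first[b] else 2, "low": 2 if high_first[b] else 1}
        side_of = {"high": "left" if high_left[b] else "right", "low": "right" if high_left[b] else "left"}
        for noise in ("high", "low") if high_first[b] else ("low", "high"):
            phase_name = f"passive_{order_of[noise]}"
            trials = simulate_partner(
                QAgentParams.preset(f"{noise}_noise"), design.structure, design.passive_trials,
                rng, phase=phase_name, block_id=bid,
            )
            phases.append(PassivePhase(order=order_of[noise], side=side_of[noise], noise=noise, trials=tuple(trials)))
        selected = str(conditions[b])
        obs = _observational_phase(
            params, kind, QAgentParams.preset(f"{selected}_noise"), design, bid, "observational",
            design.observational_trials, rng,
        )
        blocks.append(
            BlockRecord(block_id=bid, passive=tuple(sorted(phases, key=lambda x: x.order)),
                        selected_partner=selected, observational_trials=obs)
        )
    return ParticipantRecord(pid, practice_ind, practice_obs, tuple(blocks)), list(conditions)


def generate_study(
    design: StudyDesign, kind: str = "full", seed: int | None = None, params_fn=None
) -> tuple[StudyDataset, GroundTruth]:
    """Generate a complete synthetic study and its ground truth.

    ``params_fn(i, rng) -> LearnerParams`` optionally replaces the default
    prior draws (e.g. for high-identifiability validation designs).
    """
    master = design.seed if seed is None else seed
    participants = []
    param_rows = []
    block_rows = []
    for i in range(design.n_participants):
        rng = _participant_rng(master, i)
        params = draw_params(design, rng) if params_fn is None else params_fn(i, rng)
        pid = f"p{i:03d}"
        rec, conditions = generate_participant(pid, params, kind, design, rng)
        participants.append(rec)
        param_rows.append(
            {"participant_id": pid, "model_kind": kind, "alpha_v": params.alpha_v,
             "alpha_a": params.alpha_a, "w_a": params.w_a, "beta": params.beta}
        )
        for b, cond in enumerate(conditions):
            block_rows.append({"participant_id": pid, "block_id": b + 1, "partner_noise": cond})
    truth = GroundTruth(
        params=pd.DataFrame(param_rows, columns=["participant_id", "model_kind", "alpha_v", "alpha_a", "w_a", "beta"]),
        blocks=pd.DataFrame(block_rows, columns=["participant_id", "block_id", "partner_noise"]),
    )
    return StudyDataset(participants), truth
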