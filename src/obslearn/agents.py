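"""Simulated partner agents and the information-bonus RL model.

Partners are standard Q-learning agents on the three-armed bandit.  The two
candidate partners differ only in decision noise (softmax inverse
temperature): beta=1.5 for the high-noise partner, beta=20.0 for the
low-noise partner; the practice partner uses beta=7.0.  All use a learning
rate of 0.3.

The information-bonus model augments per-option values with kappa/N_X, where
N_X counts how often option X has been chosen (pseudo-count starting at 1).
It serves two roles downstream: as the participant-specific decision model
behind the partner predictability metric, and as the source of the
information-gain metric (the total reduction in bonus a choice sequence
induces).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .task_core import N_OPTIONS, RewardStructure, TrialRecord, sample_reward

#: Partner presets by condition name.
PARTNER_PRESETS = {
    "high_noise": {"alpha": 0.3, "beta": 1.5},
    "low_noise": {"alpha": 0.3, "beta": 20.0},
    "practice": {"alpha": 0.3, "beta": 7.0},
}

#: Initial Q value for partner agents: midpoint of the {0,1} reward scale.
Q_INIT = 0.5


@dataclass(frozen=True)
class QAgentParams:
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha={self.alpha} outside [0, 1]")
        if self.beta < 0:
            raise ValueError(f"beta={self.beta} must be >= 0")

    @classmethod
    def preset(cls, condition: str) -> "QAgentParams":
        if condition not in PARTNER_PRESETS:
            raise KeyError(f"unknown partner condition {condition!r}; options: {sorted(PARTNER_PRESETS)}")
        return cls(**PARTNER_PRESETS[condition])


@dataclass
class QAgentState:
    q: np.ndarray = field(default_factory=lambda: np.full(N_OPTIONS, Q_INIT))


def softmax(values: np.ndarray, beta: float) -> np.ndarray:
    """Numerically stable softmax over the last axis with inverse temperature beta."""
    z = beta * np.asarray(values, dtype=float)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def q_update(state: QAgentState, choice: int, reward: int, params: QAgentParams) -> QAgentState:
    """Delta-rule update of the chosen option's value; others unchanged."""
    q = state.q.copy()
    q[choice] += params.alpha * (reward - q[choice])
    return QAgentState(q)


def simulate_partner(
    params: QAgentParams,
    structure: RewardStructure,
    n_trials: int,
    rng: np.random.Generator,
    phase: str = "passive_1",
    block_id: int = 0,
) -> list[TrialRecord]:
    """Simulate a Q-learning partner playing ``n_trials`` bandit trials.

    Each trial: softmax choice over current Q values, Bernoulli reward from
    the structure, then a delta-rule update.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    q = np.full(N_OPTIONS, Q_INIT)
    records = []
    for t in range(n_trials):
        p = softmax(q, params.beta)
        choice = int(rng.choice(N_OPTIONS, p=p))
        reward = sample_reward(choice, structure, rng)
        q[choice] += params.alpha * (reward - q[choice])
        records.append(
            TrialRecord(block_id=block_id, trial_index=t, phase=phase, partner_choice=choice, partner_reward=reward)
        )
    return records


# -- information-bonus model -------------------------------------------------


@dataclass(frozen=True)
class InfoBonusParams:
    """Q-learning with a count-based exploration bonus kappa/N_X."""

    alpha: float
    beta: float
    kappa: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha={self.alpha} outside [0, 1]")
        if self.beta < 0:
            raise ValueError(f"beta={self.beta} must be >= 0")
        if not (0.0 <= self.kappa <= 1.0):
            raise ValueError(f"kappa={self.kappa} outside [0, 1]")


@dataclass
class InfoBonusState:
    q: np.ndarray = field(default_factory=lambda: np.full(N_OPTIONS, Q_INIT))
    n: np.ndarray = field(default_factory=lambda: np.ones(N_OPTIONS, dtype=np.int64))


def info_bonus_values(state: InfoBonusState, params: InfoBonusParams) -> np.ndarray:
    """Per-option augmented value q_X + kappa / N_X."""
    return state.q + params.kappa / state.n


def info_bonus_step(state: InfoBonusState, choice: int, reward: int, params: InfoBonusParams) -> InfoBonusState:
    """Update after observing (choice, reward): delta rule on q, count increment on n."""
    q = state.q.copy()
    n = state.n.copy()
    q[choice] += params.alpha * (reward - q[choice])
    n[choice] += 1
    return InfoBonusState(q, n)


def info_bonus_loglik(params: InfoBonusParams, choices: np.ndarray, rewards: np.ndarray) -> float:
    """Log-likelihood of a choice sequence under the information-bonus model.

    The bonus enters at decision time only (added to the value inside the
    softmax); the delta rule updates the raw q values.
    """
    state = InfoBonusState()
    total = 0.0
    for c, r in zip(np.asarray(choices), np.asarray(rewards)):
        p = softmax(info_bonus_values(state, params), params.beta)
        total += float(np.log(max(p[int(c)], 1e-300)))
        state = info_bonus_step(state, int(c), int(r), params)
    return total


def information_gain(partner_choices: np.ndarray, kappa: float) -> float:
    """Total reduction in information bonus induced by a choice sequence.

    Each choice of option X reduces its bonus by kappa * (1/N_X - 1/(N_X+1)),
    with counts starting at 1.  Telescoping gives the closed form
    kappa * sum_X (1 - 1/(c_X + 1)) for per-option counts c_X.
    """
    if not (0.0 <= kappa <= 1.0):
        raise ValueError(f"kappa={kappa} outside [0, 1]")
    n = np.ones(N_OPTIONS, dtype=np.int64)
    total = 0.0
    for c in np.asarray(partner_choices):
        c = int(c)
        total += kappa * (1.0 / n[c] - 1.0 / (n[c] + 1))
        n[c] += 1
    return total
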