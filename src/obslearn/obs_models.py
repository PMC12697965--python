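"""Observational-learning models: Full, Action Learning, Reward Learning.

The Full model carries two quantities per option X:

* an action value V_X learned from the partner's reward outcomes by a delta
  rule, ``V_X <- V_X + alpha_V (R - V_X)`` (vicarious reward learning), and
* an action tendency A_X pushed toward the partner's choices,
  ``A_chosen <- A_chosen + alpha_A (1 - A_chosen)`` and
  ``A_unchosen <- A_unchosen + alpha_A (0 - A_unchosen)`` (imitation).

Initial values are V = (1/2, 1/2, 1/2) and A = (1/3, 1/3, 1/3).  The decision
variable mixes the two systems with an imitation weight w_A,
``Q_X = (1 - w_A) V_X + w_A A_X``, passed through a softmax with inverse
temperature beta.  The Action Learning model uses A alone and the Reward
Learning model V alone (nested at w_A = 1 and w_A = 0 respectively).

Within a trial the partner acts first: the learner updates V and A from the
partner's choice and outcome, then makes its own choice.  The participant's
own outcome is never revealed and never updates state.  State resets at
every block boundary (stimuli are re-randomized across blocks).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .agents import softmax
from .task_core import N_OPTIONS, TrialRecord

MODEL_KINDS = ("full", "action_only", "reward_only")

V_INIT = 0.5
A_INIT = 1.0 / 3.0

#: Probability floor guarding log(0) at extreme inverse temperatures.
_PROB_FLOOR = 1e-300


def _check_kind(kind: str) -> None:
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}; options: {MODEL_KINDS}")


@dataclass(frozen=True)
class LearnerParams:
    """Full-model parameters; partial models ignore the irrelevant ones."""

    alpha_v: float
    alpha_a: float
    w_a: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("alpha_v", "alpha_a", "w_a"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.beta < 0:
            raise ValueError(f"beta={self.beta} must be >= 0")


@dataclass
class LearnerState:
    V: np.ndarray = field(default_factory=lambda: np.full(N_OPTIONS, V_INIT))
    A: np.ndarray = field(default_factory=lambda: np.full(N_OPTIONS, A_INIT))


def update_reward(state: LearnerState, partner_choice: int, reward: int, alpha_v: float) -> LearnerState:
    """Delta-rule update of V for the partner's chosen option; A unchanged."""
    V = state.V.copy()
    V[partner_choice] += alpha_v * (reward - V[partner_choice])
    return LearnerState(V, state.A.copy())


def update_action(state: LearnerState, partner_choice: int, alpha_a: float) -> LearnerState:
    """Contract all action tendencies toward the one-hot of the partner's choice.

    This is an affine contraction toward a probability vector, so sum(A) = 1
    is preserved exactly.
    """
    A = (1.0 - alpha_a) * state.A
    A[partner_choice] += alpha_a
    return LearnerState(state.V.copy(), A)


def decision_values(state: LearnerState, params: LearnerParams, kind: str) -> np.ndarray:
    _check_kind(kind)
    if kind == "full":
        return (1.0 - params.w_a) * state.V + params.w_a * state.A
    if kind == "action_only":
        return state.A.copy()
    return state.V.copy()


def choice_probs(state: LearnerState, params: LearnerParams, kind: str) -> np.ndarray:
    """Softmax choice probabilities of the model's decision variable."""
    return softmax(decision_values(state, params, kind), params.beta)


# -- sequence utilities -------------------------------------------------------

Block = tuple[np.ndarray, np.ndarray, np.ndarray]  # (partner_choice, partner_reward, participant_choice)


def _as_blocks(trials) -> list[Block]:
    """Normalize input to a list of per-block (pc, pr, cc) arrays.

    Accepts a single block or a list of blocks, each either an array triple
    or a sequence of TrialRecords.
    """
    if isinstance(trials, tuple) and len(trials) == 3 and isinstance(trials[0], np.ndarray):
        blocks = [trials]
    elif len(trials) > 0 and isinstance(trials[0], TrialRecord):
        blocks = [trials]
    else:
        blocks = list(trials)
    out: list[Block] = []
    for b, blk in enumerate(blocks):
        if isinstance(blk, tuple) and isinstance(blk[0], np.ndarray):
            out.append((np.asarray(blk[0]), np.asarray(blk[1]), np.asarray(blk[2])))
            continue
        pc, pr, cc = [], [], []
        for t, rec in enumerate(blk):
            if rec.partner_choice is None or rec.partner_reward is None or rec.participant_choice is None:
                raise ValueError(f"block {b}, trial {t}: incomplete observational trial record")
            pc.append(rec.partner_choice)
            pr.append(rec.partner_reward)
            cc.append(rec.participant_choice)
        out.append((np.asarray(pc), np.asarray(pr), np.asarray(cc)))
    return out


def pointwise_loglik_grid(
    alpha_v: np.ndarray,
    alpha_a: np.ndarray,
    w_a: np.ndarray,
    beta: np.ndarray,
    blocks: Sequence[tuple[np.ndarray, np.ndarray, np.ndarray]],
    kind: str = "full",
    engine: str = "auto",
) -> np.ndarray:
    """Vectorized per-trial log-likelihoods over a grid of parameter values.

    Parameters have a common shape ``(..., N)`` whose last axis indexes
    participants; each block supplies ``(pc, pr, cc)`` arrays of shape
    ``(N, T_b)``.  State resets at each block boundary.  Returns an array of
    shape ``(..., N, sum_b T_b)``.

    This is the workhorse behind both the scalar :func:`sequence_loglik` and
    the hierarchical sampler, where the leading axes are chains or posterior
    draws.  ``engine='auto'`` uses the compiled kernel when numba is
    available; ``engine='numpy'`` forces the pure-numpy reference path.
    """
    _check_kind(kind)
    alpha_v, alpha_a, w_a, beta = (np.asarray(x, dtype=float) for x in (alpha_v, alpha_a, w_a, beta))
    lead = beta.shape
    if engine == "auto":
        from . import _kernels

        if _kernels.HAVE_NUMBA and len(lead) >= 1:
            N_ = lead[-1]
            B_ = int(np.prod(lead[:-1], dtype=int)) if len(lead) > 1 else 1
            blk = [(np.atleast_2d(b[0]), np.atleast_2d(b[1]), np.atleast_2d(b[2])) for b in blocks]
            out = _kernels.obs_pointwise(
                np.broadcast_to(alpha_v, lead).reshape(B_, N_),
                np.broadcast_to(alpha_a, lead).reshape(B_, N_),
                np.broadcast_to(w_a, lead).reshape(B_, N_),
                beta.reshape(B_, N_),
                blk,
                kind,
            )
            return out.reshape(lead + (out.shape[-1],))
    N = lead[-1]
    total_T = sum(b[0].shape[-1] for b in blocks)
    out = np.empty(lead + (total_T,), dtype=float)
    idxN = np.arange(N)
    one_m_aa = 1.0 - alpha_a
    col = 0
    for pc, pr, cc in blocks:
        pc = np.atleast_2d(pc)
        pr = np.atleast_2d(pr)
        cc = np.atleast_2d(cc)
        V = np.full(lead + (N_OPTIONS,), V_INIT)
        A = np.full(lead + (N_OPTIONS,), A_INIT)
        T = pc.shape[-1]
        for t in range(T):
            c = pc[:, t]
            r = pr[:, t]
            # partner observation first: update both systems
            Vc = V[..., idxN, c]
            V[..., idxN, c] = Vc + alpha_v * (r - Vc)
            A *= one_m_aa[..., None]
            A[..., idxN, c] += alpha_a
            # then evaluate the participant's choice
            if kind == "full":
                Q = (1.0 - w_a)[..., None] * V + w_a[..., None] * A
            elif kind == "action_only":
                Q = A
            else:
                Q = V
            z = beta[..., None] * Q
            z = z - z.max(axis=-1, keepdims=True)
            e = np.exp(z)
            p = e[..., idxN, cc[:, t]] / e.sum(axis=-1)
            out[..., col] = np.log(np.maximum(p, _PROB_FLOOR))
            col += 1
    return out


def sequence_loglik(params: LearnerParams, kind: str, trials) -> tuple[float, np.ndarray]:
    """Total and per-trial log-likelihood of the participant's choices.

    ``trials`` is one block or a list of blocks (array triples or
    TrialRecord sequences); state resets at each block boundary.
    """
    blocks = _as_blocks(trials)
    grid_blocks = [(pc[None, :], pr[None, :], cc[None, :]) for pc, pr, cc in blocks]
    ll = pointwise_loglik_grid(
        np.array([params.alpha_v]),
        np.array([params.alpha_a]),
        np.array([params.w_a]),
        np.array([params.beta]),
        grid_blocks,
        kind,
    )[0]
    return float(ll.sum()), ll


def simulate_learner(
    params: LearnerParams,
    kind: str,
    partner_choices: np.ndarray,
    partner_rewards: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample a participant's choices for one block of observed partner events."""
    _check_kind(kind)
    state = LearnerState()
    choices = np.empty(len(partner_choices), dtype=np.int64)
    for t, (c, r) in enumerate(zip(partner_choices, partner_rewards)):
        state = update_reward(state, int(c), int(r), params.alpha_v)
        state = update_action(state, int(c), params.alpha_a)
        p = choice_probs(state, params, kind)
        choices[t] = rng.choice(N_OPTIONS, p=p)
    return choices
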