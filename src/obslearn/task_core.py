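"""Bandit environment, trial-level data schema, and dataset I/O.

The experiment is a three-armed Bernoulli bandit observed and played across
several phases per participant:

* ``practice_individual`` — the participant plays the bandit alone and sees
  their own outcomes (60 trials).
* ``practice_observational`` — observational learning with a fixed
  moderate-noise partner (60 trials).
* ``passive_1`` / ``passive_2`` — the participant watches two candidate
  partners (one high-noise, one low-noise) each play 30 trials.
* ``observational`` — 60 trials of observational learning with the partner
  the participant selected; the participant's own outcomes are withheld.

All phases share one tidy CSV schema (one row per trial) so the whole
pipeline reads and writes a single file per study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

N_OPTIONS = 3
OPTION_IDS = (0, 1, 2)

PHASES = (
    "practice_individual",
    "practice_observational",
    "passive_1",
    "passive_2",
    "observational",
)

#: Columns of the tidy trial-level CSV, in canonical order.
CSV_COLUMNS = [
    "participant_id",
    "block_id",
    "phase",
    "trial_index",
    "partner_noise",
    "partner_side",
    "partner_choice",
    "partner_reward",
    "participant_choice",
    "selected_partner",
]

_NULLABLE_INT = {"partner_choice", "partner_reward", "participant_choice", "trial_index", "block_id"}


class SchemaError(ValueError):
    """A dataset row violates the trial-level schema."""


@dataclass(frozen=True)
class RewardStructure:
    """Per-option Bernoulli reward probabilities of the three-armed bandit.

    The default (0.25, 0.50, 0.75) is the structure used in every task phase.
    """

    probs: tuple[float, float, float] = (0.25, 0.50, 0.75)

    def __post_init__(self) -> None:
        if len(self.probs) != N_OPTIONS:
            raise ValueError(f"expected {N_OPTIONS} reward probabilities, got {len(self.probs)}")
        for p in self.probs:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"reward probability {p} outside [0, 1]")

    def best_option(self) -> int:
        """Index of the option with maximal reward probability (ties: lowest index)."""
        return int(np.argmax(self.probs))


def sample_reward(option: int, structure: RewardStructure, rng: np.random.Generator) -> int:
    """Draw a {0,1} reward for ``option`` from its Bernoulli probability."""
    if option not in OPTION_IDS:
        raise ValueError(f"invalid option id {option!r}; must be one of {OPTION_IDS}")
    return int(rng.random() < structure.probs[option])


def proportion_correct(choices: Sequence[int], structure: RewardStructure) -> float:
    """Fraction of choices equal to the best option of ``structure``."""
    arr = np.asarray(choices)
    if arr.size == 0:
        raise ValueError("proportion_correct: empty choice sequence")
    return float(np.mean(arr == structure.best_option()))


@dataclass(frozen=True)
class TrialRecord:
    """One trial of any phase.

    ``partner_reward`` holds the revealed outcome of the acting agent: the
    partner's outcome in observational/passive phases, the participant's own
    outcome in the practice individual phase (where no partner exists).
    """

    block_id: int
    trial_index: int
    phase: str
    partner_choice: int | None = None
    partner_reward: int | None = None
    participant_choice: int | None = None

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise SchemaError(f"unknown phase {self.phase!r}")
        for name in ("partner_choice", "participant_choice"):
            v = getattr(self, name)
            if v is not None and v not in OPTION_IDS:
                raise SchemaError(f"{name}={v!r} not a valid option id")
        if self.partner_reward is not None and self.partner_reward not in (0, 1):
            raise SchemaError(f"partner_reward={self.partner_reward!r} not in {{0,1}}")
        if self.phase in ("passive_1", "passive_2") and self.participant_choice is not None:
            raise SchemaError("passive-phase records carry no participant_choice")


@dataclass(frozen=True)
class PassivePhase:
    """One candidate partner's 30-trial demonstration within a block."""

    order: int  # 1 = shown first, 2 = shown second
    side: str  # 'left' or 'right' in the selection screen
    noise: str  # 'high' or 'low'
    trials: tuple[TrialRecord, ...]


@dataclass(frozen=True)
class BlockRecord:
    """One main block: two passive demonstrations, a selection, and the
    observational-learning phase with the selected partner."""

    block_id: int
    passive: tuple[PassivePhase, PassivePhase]
    selected_partner: str  # 'high' or 'low'
    observational_trials: tuple[TrialRecord, ...]

    def __post_init__(self) -> None:
        noises = {p.noise for p in self.passive}
        if noises != {"high", "low"}:
            raise SchemaError(f"block {self.block_id}: passive partners must be one high- and one low-noise, got {noises}")
        if self.selected_partner not in ("high", "low"):
            raise SchemaError(f"block {self.block_id}: selected_partner={self.selected_partner!r}")

    @property
    def selected_side(self) -> str:
        return next(p.side for p in self.passive if p.noise == self.selected_partner)


@dataclass(frozen=True)
class ParticipantRecord:
    participant_id: str
    practice_individual: tuple[TrialRecord, ...]
    practice_observational: tuple[TrialRecord, ...]
    blocks: tuple[BlockRecord, ...]

    @property
    def preference(self) -> float:
        """Proportion of blocks in which the high-noise partner was selected."""
        if not self.blocks:
            return float("nan")
        return float(np.mean([b.selected_partner == "high" for b in self.blocks]))


@dataclass
class StudyDataset:
    """A complete study: a list of participants, plus tidy-frame conversion."""

    participants: list[ParticipantRecord] = field(default_factory=list)

    # -- frame conversion ---------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows: list[dict] = []

        def trial_row(pid: str, t: TrialRecord, noise=None, side=None, selected=None) -> dict:
            return {
                "participant_id": pid,
                "block_id": t.block_id,
                "phase": t.phase,
                "trial_index": t.trial_index,
                "partner_noise": noise,
                "partner_side": side,
                "partner_choice": t.partner_choice,
                "partner_reward": t.partner_reward,
                "participant_choice": t.participant_choice,
                "selected_partner": selected,
            }

        for p in self.participants:
            for t in p.practice_individual:
                rows.append(trial_row(p.participant_id, t))
            for t in p.practice_observational:
                rows.append(trial_row(p.participant_id, t))
            for b in p.blocks:
                for ph in sorted(b.passive, key=lambda x: x.order):
                    for t in ph.trials:
                        rows.append(
                            trial_row(p.participant_id, t, noise=ph.noise, side=ph.side, selected=b.selected_partner)
                        )
                for t in b.observational_trials:
                    rows.append(
                        trial_row(p.participant_id, t, noise=b.selected_partner, selected=b.selected_partner)
                    )
        frame = pd.DataFrame(rows, columns=CSV_COLUMNS)
        for col in _NULLABLE_INT:
            frame[col] = frame[col].astype("Int64")
        frame["participant_id"] = frame["participant_id"].astype(str)
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "StudyDataset":
        _validate_frame(frame)
        participants: list[ParticipantRecord] = []
        for pid, g in frame.groupby("participant_id", sort=False):
            participants.append(_participant_from_frame(str(pid), g))
        return cls(participants)

    # -- accessors ----------------------------------------------------------

    @property
    def participant_ids(self) -> list[str]:
        return [p.participant_id for p in self.participants]

    def participant(self, pid: str) -> ParticipantRecord:
        for p in self.participants:
            if p.participant_id == pid:
                return p
        raise KeyError(pid)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StudyDataset):
            return NotImplemented
        return self.participants == other.participants

    def __len__(self) -> int:
        return len(self.participants)


def _validate_frame(frame: pd.DataFrame) -> None:
    if frame.empty:
        raise SchemaError("no records")
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    for idx, row in frame.iterrows():
        phase = row["phase"]
        if phase not in PHASES:
            raise SchemaError(f"row {idx}, column 'phase': unknown phase {phase!r}")
        for col in ("partner_choice", "participant_choice"):
            v = row[col]
            if pd.notna(v) and int(v) not in OPTION_IDS:
                raise SchemaError(f"row {idx}, column '{col}': {v} not a valid option id")
        v = row["partner_reward"]
        if pd.notna(v) and int(v) not in (0, 1):
            raise SchemaError(f"row {idx}, column 'partner_reward': {v} not in {{0,1}}")
        if phase in ("passive_1", "passive_2") and pd.notna(row["participant_choice"]):
            raise SchemaError(f"row {idx}, column 'participant_choice': must be NA in phase {phase}")


def _trials_from_rows(g: pd.DataFrame, phase: str) -> tuple[TrialRecord, ...]:
    out = []
    for _, row in g.sort_values("trial_index").iterrows():
        out.append(
            TrialRecord(
                block_id=int(row["block_id"]),
                trial_index=int(row["trial_index"]),
                phase=phase,
                partner_choice=None if pd.isna(row["partner_choice"]) else int(row["partner_choice"]),
                partner_reward=None if pd.isna(row["partner_reward"]) else int(row["partner_reward"]),
                participant_choice=None if pd.isna(row["participant_choice"]) else int(row["participant_choice"]),
            )
        )
    return tuple(out)


def _participant_from_frame(pid: str, g: pd.DataFrame) -> ParticipantRecord:
    practice_ind = _trials_from_rows(g[g["phase"] == "practice_individual"], "practice_individual")
    practice_obs = _trials_from_rows(g[g["phase"] == "practice_observational"], "practice_observational")
    blocks = []
    main = g[g["phase"].isin(["passive_1", "passive_2", "observational"])]
    for bid, bg in main.groupby("block_id", sort=True):
        passive = []
        for order, phase in ((1, "passive_1"), (2, "passive_2")):
            pg = bg[bg["phase"] == phase]
            if pg.empty:
                raise SchemaError(f"participant {pid} block {bid}: missing {phase} rows")
            noise = pg["partner_noise"].iloc[0]
            side = pg["partner_side"].iloc[0]
            passive.append(PassivePhase(order=order, side=str(side), noise=str(noise), trials=_trials_from_rows(pg, phase)))
        og = bg[bg["phase"] == "observational"]
        if og.empty:
            raise SchemaError(f"participant {pid} block {bid}: missing observational rows")
        selected = str(og["selected_partner"].iloc[0])
        blocks.append(
            BlockRecord(
                block_id=int(bid),
                passive=tuple(passive),
                selected_partner=selected,
                observational_trials=_trials_from_rows(og, "observational"),
            )
        )
    return ParticipantRecord(pid, practice_ind, practice_obs, tuple(blocks))


def write_dataset(dataset: StudyDataset, path: str | Path) -> None:
    """Write a study to tidy CSV (UTF-8, NA for missing cells)."""
    frame = dataset.to_frame()
    frame.to_csv(path, index=False, na_rep="NA")


def read_dataset(path: str | Path) -> StudyDataset:
    """Read a tidy study CSV written by :func:`write_dataset`."""
    try:
        frame = pd.read_csv(path, na_values=["NA"], keep_default_na=True, dtype={"participant_id": str})
    except pd.errors.EmptyDataError:
        raise SchemaError("no records") from None
    if frame.empty:
        raise SchemaError("no records")
    for col in _NULLABLE_INT:
        if col in frame.columns:
            frame[col] = frame[col].astype("Int64")
    return StudyDataset.from_frame(frame)


# -- array extraction helpers used by the model-fitting stages ---------------


def observational_arrays(p: ParticipantRecord) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per main block: (partner_choice, partner_reward, participant_choice) int arrays."""
    out = []
    for b in p.blocks:
        pc = np.array([t.partner_choice for t in b.observational_trials], dtype=np.int64)
        pr = np.array([t.partner_reward for t in b.observational_trials], dtype=np.int64)
        cc = np.array([t.participant_choice for t in b.observational_trials], dtype=np.int64)
        out.append((pc, pr, cc))
    return out


def practice_individual_arrays(p: ParticipantRecord) -> tuple[np.ndarray, np.ndarray]:
    """(own_choice, own_reward) arrays for the practice individual phase."""
    ch = np.array([t.participant_choice for t in p.practice_individual], dtype=np.int64)
    rw = np.array([t.partner_reward for t in p.practice_individual], dtype=np.int64)
    return ch, rw


def passive_arrays(ph: PassivePhase) -> tuple[np.ndarray, np.ndarray]:
    pc = np.array([t.partner_choice for t in ph.trials], dtype=np.int64)
    pr = np.array([t.partner_reward for t in ph.trials], dtype=np.int64)
    return pc, pr


def learning_curve(dataset: StudyDataset, structure: RewardStructure | None = None) -> np.ndarray:
    """Per-trial proportion of correct observational choices, averaged over
    participants and blocks."""
    structure = structure or RewardStructure()
    best = structure.best_option()
    curves = []
    for p in dataset.participants:
        for b in p.blocks:
            curves.append([int(t.participant_choice == best) for t in b.observational_trials])
    if not curves:
        raise ValueError("dataset has no observational trials")
    return np.asarray(curves, dtype=float).mean(axis=0)
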