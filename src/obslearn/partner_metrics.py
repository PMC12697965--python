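"""Block-level partner indices: performance, predictability, information gain.

Each candidate partner in each block gets three scores derived from its
30-trial passive demonstration:

* performance — total reward obtained;
* predictability — the log-likelihood that the observer's own decision
  process (the information-bonus model fitted to their practice
  individual-learning data) would generate the partner's choices;
* information gain — the total reduction in the observer's information
  bonus induced by the partner's choices (a proxy for how much directed
  exploration the demonstration embodies).

The selection regressions use right-minus-left difference scores of these
indices, z-standardized across all participant-blocks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .agents import InfoBonusParams, info_bonus_loglik, information_gain
from .hier_fit import FitResult, fit_individual
from .task_core import StudyDataset, passive_arrays

METRIC_NAMES = ("performance", "predictability", "information_gain")


def performance(rewards: np.ndarray) -> int:
    """Total reward obtained over a passive demonstration."""
    arr = np.asarray(rewards)
    if arr.size and not np.isin(arr, (0, 1)).all():
        raise ValueError("rewards must be in {0, 1}")
    return int(arr.sum())


def predictability(params: InfoBonusParams, partner_choices: np.ndarray, partner_rewards: np.ndarray) -> float:
    """Log-likelihood of the partner's choices under the observer's model.

    The observer's model state updates from the partner's choices and
    rewards as the demonstration unfolds (the observer sees both).
    """
    return info_bonus_loglik(params, partner_choices, partner_rewards)


def participant_params(fit: FitResult, pid: str) -> InfoBonusParams:
    """Posterior-mean information-bonus parameters for one participant."""
    row = fit.participant_means.loc[pid]
    return InfoBonusParams(alpha=float(row["alpha"]), beta=float(row["beta"]), kappa=float(row["kappa"]))


def partner_metrics_table(dataset: StudyDataset, indiv_fit: FitResult) -> pd.DataFrame:
    """One row per (participant, block, side): the three partner indices.

    ``indiv_fit`` is the hierarchical information-bonus fit to the practice
    individual-learning phase (see :func:`obslearn.hier_fit.fit_individual`).
    """
    rows = []
    for p in dataset.participants:
        params = participant_params(indiv_fit, p.participant_id)
        for b in p.blocks:
            for ph in b.passive:
                pc, pr = passive_arrays(ph)
                rows.append(
                    {
                        "participant_id": p.participant_id,
                        "block_id": b.block_id,
                        "side": ph.side,
                        "order": ph.order,
                        "partner_noise": ph.noise,
                        "selected_partner": b.selected_partner,
                        "performance": performance(pr),
                        "predictability": predictability(params, pc, pr),
                        "information_gain": information_gain(pc, params.kappa),
                    }
                )
    return pd.DataFrame(rows)


def selection_regressors(metrics: pd.DataFrame, standardize: bool = True) -> pd.DataFrame:
    """Per-block right-minus-left difference scores of the three indices.

    Differences are z-standardized across all participant-blocks pooled
    (each regressor to mean 0, sd 1) unless ``standardize`` is False.
    """
    wide = metrics.pivot_table(
        index=["participant_id", "block_id"], columns="side", values=list(METRIC_NAMES), sort=False
    )
    out = pd.DataFrame(index=wide.index)
    for name in METRIC_NAMES:
        if ("right" not in wide[name]) or wide[name][["left", "right"]].isna().any().any():
            raise ValueError(f"selection_regressors: both sides required for index {name!r}")
        diff = wide[name]["right"] - wide[name]["left"]
        if standardize:
            sd = diff.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                raise ValueError(f"selection_regressors: zero variance in index {name!r}")
            diff = (diff - diff.mean()) / sd
        out[f"d_{name}"] = diff
    return out.reset_index()


def fit_practice_individual(dataset: StudyDataset, chains=4, warmup=1000, draws=1000, seed=0) -> FitResult:
    """Convenience wrapper: hierarchical information-bonus fit on practice data."""
    return fit_individual(dataset, chains=chains, warmup=warmup, draws=draws, seed=seed)
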