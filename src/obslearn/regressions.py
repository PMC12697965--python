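"""Partner-selection and learning-style regressions.

Selection models (one row per participant-block; outcome Y = 1 if the
left-hand partner was chosen):

* Model 1: Y ~ X1, where X1 = +1 if the high-noise partner appeared on the
  left, -1 otherwise (a negative coefficient means low-noise partners are
  preferred);
* Model 2: adds X2 = +1 if the left partner was shown first in the passive
  observation phase;
* factor model: X1 replaced by z-scored right-minus-left differences of the
  three partner indices (performance, predictability, information gain).

Learning-style GLMMs (one mixed logistic per option X, coefficients pooled
across options by inverse-variance weighting):

* between-participant: logit P(choice = X) ~ 1 + (C + R) * P with
  by-participant random intercepts and C/R slopes, where C = +1 if the
  partner chose X on that trial (else -1), R = +1 if the partner was
  rewarded for X, -1 if rewarded for another option, 0 if unrewarded, and
  P is the participant's proportion of high-noise-partner blocks
  (uncentered, so effects are interpretable at P = 0);
* within-participant: logit P(choice = X) ~ 1 + (C + R) * D with D = +1 for
  a high-noise block and -1 for a low-noise block, restricted to
  participants who experienced both partner types.

Mixed-model estimation is delegated to statsmodels' variational-Bayes mixed
GLM; a fixed-effects GLM with cluster-robust standard errors serves as the
fallback for degenerate random-effects structures (flagged in the output).
Coefficient tests are two-tailed t-tests with degrees of freedom equal to
the number of participants (a reporting convention, not derived).
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .task_core import StudyDataset, proportion_correct  # noqa: F401  (re-exported convenience)

__all__ = [
    "EffectEstimate",
    "LogisticFit",
    "build_selection_design",
    "build_learning_style_design",
    "fit_mixed_logistic",
    "optionwise_glmm",
    "pool_effects",
    "marginal_effects",
    "cohens_d",
    "power_bootstrap",
    "simulate_selection",
    "ttest_vs_chance",
]


@dataclass(frozen=True)
class EffectEstimate:
    term: str
    estimate: float
    se: float
    stat: float
    df: int
    p: float
    engine: str
    pooled: bool = False


@dataclass
class LogisticFit:
    terms: list[str]
    params: np.ndarray
    cov: np.ndarray  # full covariance (GLM) or diagonal (VB posterior sds)
    df: int
    engine: str  # 'vb_mixed' or 'glm_cluster'
    effects: list[EffectEstimate]
    flagged: bool = False  # True when the mixed fit fell back or misbehaved
    vc_sd: dict = field(default_factory=dict)  # random-effect sds by term

    def effect(self, term: str) -> EffectEstimate:
        for e in self.effects:
            if e.term == term:
                return e
        raise KeyError(term)


def _two_tailed_p(stat: float, df: int) -> float:
    return float(2.0 * stats.t.sf(abs(stat), df))


# -- design builders ---------------------------------------------------------


def build_selection_design(
    dataset: StudyDataset, which: str = "model2", metrics: pd.DataFrame | None = None
) -> pd.DataFrame:
    """One coded row per participant-block for the selection regressions.

    ``metrics`` (required for ``which='factors'``) is the output of
    :func:`obslearn.partner_metrics.selection_regressors`.
    """
    if which not in ("model1", "model2", "factors"):
        raise ValueError(f"unknown selection model {which!r}")
    rows = []
    for p in dataset.participants:
        for b in p.blocks:
            if b.selected_partner not in ("high", "low"):
                raise ValueError(f"participant {p.participant_id} block {b.block_id}: missing selection")
            high = next(ph for ph in b.passive if ph.noise == "high")
            left = next(ph for ph in b.passive if ph.side == "left")
            rows.append(
                {
                    "participant_id": p.participant_id,
                    "block_id": b.block_id,
                    "Y": int(b.selected_side == "left"),
                    "X1": 1 if high.side == "left" else -1,
                    "X2": 1 if left.order == 1 else -1,
                }
            )
    frame = pd.DataFrame(rows)
    if which == "factors":
        if metrics is None:
            raise ValueError("factor model requires the partner-metric difference scores")
        frame = frame.merge(metrics, on=["participant_id", "block_id"], validate="one_to_one")
    return frame


SELECTION_TERMS = {
    "model1": ["X1"],
    "model2": ["X1", "X2"],
    "factors": ["d_performance", "d_predictability", "d_information_gain", "X2"],
}


def build_learning_style_design(dataset: StudyDataset, moderator: str = "P") -> dict[int, pd.DataFrame]:
    """Per-option trial tables for the learning-style GLMMs.

    Returns {option: frame} with columns Y, C, R, M (the moderator value),
    participant_id.  With ``moderator='D'`` the table is restricted to
    participants who selected both high- and low-noise partners at least
    once.
    """
    if moderator not in ("P", "D"):
        raise ValueError(f"unknown moderator {moderator!r}")
    base_rows = []
    for p in dataset.participants:
        pref = p.preference
        if moderator == "D":
            conds = {b.selected_partner for b in p.blocks}
            if conds != {"high", "low"}:
                continue
        for b in p.blocks:
            d = 1 if b.selected_partner == "high" else -1
            for t in b.observational_trials:
                base_rows.append(
                    {
                        "participant_id": p.participant_id,
                        "partner_choice": t.partner_choice,
                        "partner_reward": t.partner_reward,
                        "participant_choice": t.participant_choice,
                        "M": pref if moderator == "P" else d,
                    }
                )
    if not base_rows:
        raise ValueError("no eligible observational trials for the learning-style design")
    base = pd.DataFrame(base_rows)
    out = {}
    for option in (0, 1, 2):
        f = pd.DataFrame(
            {
                "participant_id": base["participant_id"],
                "Y": (base["participant_choice"] == option).astype(int),
                "C": np.where(base["partner_choice"] == option, 1, -1),
                "R": np.where(
                    base["partner_reward"] == 0, 0, np.where(base["partner_choice"] == option, 1, -1)
                ),
                "M": base["M"],
            }
        )
        out[option] = f
    return out


# -- estimation engines ------------------------------------------------------


def _fit_vb(frame, response, fixed_terms, group_col, random_slopes):
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    y = frame[response].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(frame))] + [frame[t].to_numpy(dtype=float) for t in fixed_terms])
    groups = pd.Categorical(frame[group_col])
    G = len(groups.categories)
    dummies = np.eye(G)[groups.codes]
    vc_blocks = [dummies]
    vc_names = ["intercept"]
    for term in random_slopes or []:
        vc_blocks.append(dummies * frame[term].to_numpy(dtype=float)[:, None])
        vc_names.append(term)
    exog_vc = np.concatenate(vc_blocks, axis=1)
    ident = np.concatenate([np.full(G, i) for i in range(len(vc_blocks))])
    model = BinomialBayesMixedGLM(y, X, exog_vc, ident, vcp_p=2.0, fe_p=2.0)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        res = model.fit_vb()
    params = res.fe_mean
    sds = res.fe_sd
    vc_sd = {name: float(np.exp(res.vcp_mean[i])) for i, name in enumerate(vc_names)}
    flagged = bool(np.any(~np.isfinite(params)) or np.any(np.abs(params) > 15))
    return params, np.diag(sds**2), G, "vb_mixed", flagged, vc_sd


def _fit_glm_cluster(frame, response, fixed_terms, group_col):
    import statsmodels.api as sm

    y = frame[response].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(frame))] + [frame[t].to_numpy(dtype=float) for t in fixed_terms])
    groups = pd.Categorical(frame[group_col]).codes
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
            cov_type="cluster", cov_kwds={"groups": groups}
        )
    G = len(np.unique(groups))
    flagged = bool(np.any(np.abs(res.params) > 15))
    return np.asarray(res.params), np.asarray(res.cov_params()), G, "glm_cluster", flagged, {}


def fit_mixed_logistic(
    frame: pd.DataFrame,
    response: str = "Y",
    fixed_terms: Sequence[str] = ("X1",),
    group_col: str = "participant_id",
    random_slopes: Sequence[str] | None = None,
    engine: str = "auto",
) -> LogisticFit:
    """Mixed-effects logistic regression with by-participant random
    intercepts and (by default) random slopes for every fixed effect.

    ``engine``: 'auto' tries the variational mixed fit and falls back to a
    fixed-effects GLM with cluster-robust standard errors (flagged);
    'vb' / 'glm' force one engine.
    """
    fixed_terms = list(fixed_terms)
    if frame[group_col].nunique() < 2:
        raise ValueError("mixed logistic requires >= 2 participants")
    if random_slopes is None:
        random_slopes = fixed_terms
    flagged = False
    if engine in ("auto", "vb"):
        try:
            params, cov, G, used, flagged, vc_sd = _fit_vb(frame, response, fixed_terms, group_col, random_slopes)
            if flagged and engine == "auto":
                raise RuntimeError("degenerate variational fit")
        except Exception:
            if engine == "vb":
                raise
            params, cov, G, used, flagged, vc_sd = _fit_glm_cluster(frame, response, fixed_terms, group_col)
            flagged = True
    else:
        params, cov, G, used, flagged, vc_sd = _fit_glm_cluster(frame, response, fixed_terms, group_col)
    terms = ["intercept"] + fixed_terms
    se = np.sqrt(np.diag(cov))
    effects = [
        EffectEstimate(
            term=t,
            estimate=float(params[i]),
            se=float(se[i]),
            stat=float(params[i] / se[i]),
            df=G,
            p=_two_tailed_p(params[i] / se[i], G),
            engine=used,
        )
        for i, t in enumerate(terms)
    ]
    return LogisticFit(terms=terms, params=np.asarray(params), cov=np.asarray(cov), df=G,
                       engine=used, effects=effects, flagged=flagged, vc_sd=vc_sd)


# -- option-wise GLMMs and pooling -------------------------------------------


@dataclass
class OptionwiseResult:
    per_option: dict[int, LogisticFit]
    pooled: list[EffectEstimate]

    def pooled_effect(self, term: str) -> EffectEstimate:
        for e in self.pooled:
            if e.term == term:
                return e
        raise KeyError(term)


def optionwise_glmm(dataset: StudyDataset, moderator: str = "P", engine: str = "auto") -> OptionwiseResult:
    """Three option-wise learning-style GLMMs plus pooled effects.

    Fixed effects: intercept, C, R, M, C:M, R:M; random intercepts and C/R
    slopes by participant (plus M-interaction slopes for the
    within-participant moderator D).
    """
    designs = build_learning_style_design(dataset, moderator)
    fits = {}
    for option, f in designs.items():
        f = f.assign(**{"C:M": f["C"] * f["M"], "R:M": f["R"] * f["M"]})
        slopes = ["C", "R"] if moderator == "P" else ["C", "R", "M", "C:M", "R:M"]
        fits[option] = fit_mixed_logistic(
            f, "Y", ["C", "R", "M", "C:M", "R:M"], random_slopes=slopes, engine=engine
        )
    terms = fits[0].terms
    pooled = [pool_effects([fits[o].effect(t) for o in (0, 1, 2)]) for t in terms]
    return OptionwiseResult(per_option=fits, pooled=pooled)


def pool_effects(effects: Sequence[EffectEstimate]) -> EffectEstimate:
    """Inverse-variance-weighted average of parallel coefficients.

    Weights 1/SE^2; pooled SE = sqrt(1 / sum of weights).
    """
    if any(e.se <= 0 for e in effects):
        raise ValueError("pool_effects: standard errors must be positive")
    w = np.array([1.0 / e.se**2 for e in effects])
    b = float(np.sum(w * [e.estimate for e in effects]) / w.sum())
    se = float(np.sqrt(1.0 / w.sum()))
    df = min(e.df for e in effects)
    stat = b / se
    return EffectEstimate(
        term=effects[0].term, estimate=b, se=se, stat=stat, df=df,
        p=_two_tailed_p(stat, df), engine=effects[0].engine, pooled=True,
    )


def marginal_effects(
    fit: LogisticFit, main_term: str, interaction_term: str, moderator_values: Sequence[float]
) -> pd.DataFrame:
    """Simple slopes of ``main_term`` at given moderator levels.

    slope(m) = b_main + m * b_interaction, with the SE propagated from the
    coefficient covariance (the VB engine provides a diagonal covariance,
    so the cross term is zero there).
    """
    i = fit.terms.index(main_term)
    j = fit.terms.index(interaction_term)
    rows = []
    for m in moderator_values:
        slope = fit.params[i] + m * fit.params[j]
        var = fit.cov[i, i] + m**2 * fit.cov[j, j] + 2 * m * fit.cov[i, j]
        se = float(np.sqrt(var))
        rows.append({"moderator": m, "slope": float(slope), "se": se,
                     "stat": float(slope / se), "p": _two_tailed_p(slope / se, fit.df)})
    return pd.DataFrame(rows)


# -- simple statistics -------------------------------------------------------


def cohens_d(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Standardized mean difference with the pooled standard deviation."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("cohens_d requires >= 2 observations per group")
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        raise ValueError("cohens_d: zero pooled standard deviation")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def ttest_vs_chance(proportions: Sequence[float], chance: float = 1.0 / 3.0):
    """One-sample two-tailed t-test of participant proportions against chance.

    Returns (t, df, p).
    """
    arr = np.asarray(proportions, dtype=float)
    if len(arr) < 2:
        raise ValueError("ttest_vs_chance requires >= 2 participants")
    if arr.std(ddof=1) == 0 and arr.mean() == chance:
        return 0.0, len(arr) - 1, 1.0  # exactly at chance with no spread
    res = stats.ttest_1samp(arr, chance)
    return float(res.statistic), len(arr) - 1, float(res.pvalue)


# -- power analysis ----------------------------------------------------------


def simulate_selection(
    n_participants: int,
    n_blocks: int,
    intercept: float,
    noise_effect: float,
    sd_intercept: float,
    sd_slope: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate selection-design rows from a mixed logistic generator.

    The high-noise partner's side (X1) is counterbalanced within participant;
    Y is drawn from logit(p) = (b0 + u0) + (b1 + u1) X1 with participant
    effects u ~ Normal(0, sd).
    """
    rows = []
    for i in range(n_participants):
        u0 = rng.normal(0, sd_intercept) if sd_intercept > 0 else 0.0
        u1 = rng.normal(0, sd_slope) if sd_slope > 0 else 0.0
        x1 = np.ones(n_blocks, dtype=int)
        x1[: n_blocks // 2] = -1
        rng.shuffle(x1)
        for b in range(n_blocks):
            logit = (intercept + u0) + (noise_effect + u1) * x1[b]
            y = int(rng.random() < 1.0 / (1.0 + np.exp(-logit)))
            rows.append({"participant_id": f"s{i:03d}", "block_id": b + 1, "Y": y, "X1": int(x1[b])})
    return pd.DataFrame(rows)


def power_bootstrap(
    fit: LogisticFit,
    n_values: Sequence[int],
    n_boot: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    n_blocks: int = 4,
    engine: str = "glm",
) -> pd.DataFrame:
    """Bootstrap power for the Model 1 noise-level effect at candidate
    sample sizes, simulating from a fitted selection model (fixed effects
    plus participant random effects)."""
    b0 = fit.effect("intercept").estimate
    b1 = fit.effect("X1").estimate
    sd0 = fit.vc_sd.get("intercept", 0.0)
    sd1 = fit.vc_sd.get("X1", 0.0)
    rows = []
    rng = np.random.default_rng(seed)
    for n in n_values:
        hits = 0
        for _ in range(n_boot):
            sim = simulate_selection(n, n_blocks, b0, b1, sd0, sd1, rng)
            refit = fit_mixed_logistic(sim, "Y", ["X1"], engine=engine)
            if refit.effect("X1").p < alpha:
                hits += 1
        rows.append({"n": n, "power": hits / n_boot})
    return pd.DataFrame(rows)
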