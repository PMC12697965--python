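"""Hierarchical Bayesian fitting of choice models and WAIC comparison.

Individual-level parameters are sampled on an unconstrained (raw) scale and
transformed to their domains: a logistic transform for unit-interval
parameters (learning rates, the imitation weight w_A, the bonus weight
kappa) and an exponential transform for the positive inverse temperature.
Raw parameters are modeled as Normal(mu_theta, sigma_theta^2) across
participants, with weakly informative hyperpriors mu ~ Normal(0, 1) and
sigma ~ Half-Cauchy(0, 3).

Sampling uses a blocked adaptive Metropolis-within-Gibbs scheme, vectorized
across chains and participants:

1. each participant's raw-parameter vector is updated jointly by a
   random-walk Metropolis step (participants are conditionally independent
   given the hyperparameters, so all are updated in parallel);
2. the population means have a conjugate Normal full conditional and are
   updated by an exact Gibbs draw;
3. the population standard deviations are updated by a Metropolis step on
   the log scale;
4. an interleaved non-centered step jointly moves (mu, sigma) while holding
   the standardized participant effects eta = (theta - mu)/sigma fixed,
   which breaks the funnel-shaped coupling between sigma and the
   participant-level parameters (ancillarity-sufficiency interleaving).

Proposal scales adapt toward a target acceptance rate during warmup only,
so retained draws come from a fixed transition kernel.  Convergence is
summarized by split R-hat and effective sample size (arviz); fits with any
R-hat above 1.05 carry a warning rather than raising.

Model comparison uses WAIC computed from per-trial pointwise posterior
log-likelihoods: lppd = sum_t log mean_d exp(ll_dt), p_waic = sum_t
var_d(ll_dt), waic = -2 (lppd - p_waic).
"""

from __future__ import annotations

import json as _json
import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from . import obs_models
from .task_core import (
    StudyDataset,
    observational_arrays,
    practice_individual_arrays,
)

_LOG_2PI = float(np.log(2.0 * np.pi))

MU_PRIOR_SD = 1.0
SIGMA_CAUCHY_SCALE = 3.0
RHAT_THRESHOLD = 1.05


# -- transforms ---------------------------------------------------------------


def to_natural(theta_raw, transform: str):
    """Map a raw-scale value to its natural domain."""
    from scipy.special import expit

    x = np.asarray(theta_raw, dtype=float)
    if transform == "logistic":
        out = expit(x)
    elif transform == "exp":
        with np.errstate(over="ignore"):  # inf maps to a rejected proposal
            out = np.exp(x)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    return out if out.ndim else float(out)


def to_raw(value, transform: str):
    """Inverse of :func:`to_natural`."""
    x = np.asarray(value, dtype=float)
    if transform == "logistic":
        out = np.log(x) - np.log1p(-x)
    elif transform == "exp":
        out = np.log(x)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ParamSpec:
    name: str
    transform: str  # 'logistic' or 'exp'


class HierModel(Protocol):
    """A likelihood adapter the hierarchical sampler can fit."""

    name: str
    specs: tuple[ParamSpec, ...]

    def prepare(self, dataset: StudyDataset):
        """Extract per-participant trial arrays from a study."""

    def pointwise(self, natural: dict[str, np.ndarray], data) -> np.ndarray:
        """Per-trial log-likelihoods, shape ``lead + (n_trials,)`` where the
        natural parameter arrays share shape ``lead = (..., n_participants)``."""


class ObsLearningModel:
    """Adapter for the three observational-learning models."""

    _SPEC_SETS = {
        "full": (
            ParamSpec("alpha_v", "logistic"),
            ParamSpec("alpha_a", "logistic"),
            ParamSpec("w_a", "logistic"),
            ParamSpec("beta", "exp"),
        ),
        "action_only": (ParamSpec("alpha_a", "logistic"), ParamSpec("beta", "exp")),
        "reward_only": (ParamSpec("alpha_v", "logistic"), ParamSpec("beta", "exp")),
    }

    def __init__(self, kind: str):
        if kind not in self._SPEC_SETS:
            raise ValueError(f"unknown model kind {kind!r}")
        self.kind = kind
        self.name = kind
        self.specs = self._SPEC_SETS[kind]

    def prepare(self, dataset: StudyDataset):
        """Stack observational blocks into per-block (N, T) arrays.

        Requires every participant to share the block/trial layout (true for
        both the task design and the synthetic generator).
        """
        per_part = [observational_arrays(p) for p in dataset.participants]
        if not per_part or not per_part[0]:
            raise ValueError("dataset has no observational trials")
        n_blocks = len(per_part[0])
        if any(len(bl) != n_blocks for bl in per_part):
            raise ValueError("participants differ in number of observational blocks")
        blocks = []
        for b in range(n_blocks):
            pc = np.stack([bl[b][0] for bl in per_part])
            pr = np.stack([bl[b][1] for bl in per_part])
            cc = np.stack([bl[b][2] for bl in per_part])
            blocks.append((pc, pr, cc))
        return blocks

    def pointwise(self, natural: dict[str, np.ndarray], data) -> np.ndarray:
        beta = natural["beta"]
        zeros = np.zeros_like(beta)
        return obs_models.pointwise_loglik_grid(
            natural.get("alpha_v", zeros),
            natural.get("alpha_a", zeros),
            natural.get("w_a", zeros),
            beta,
            data,
            self.kind,
        )


class InfoBonusModel:
    """Adapter for the individual-learning model with a count-based bonus.

    Fitted to the practice individual-learning phase; used downstream for the
    partner predictability and information-gain metrics.
    """

    name = "info_bonus"
    specs = (
        ParamSpec("alpha", "logistic"),
        ParamSpec("beta", "exp"),
        ParamSpec("kappa", "logistic"),
    )

    def prepare(self, dataset: StudyDataset):
        pairs = [practice_individual_arrays(p) for p in dataset.participants]
        if not pairs or pairs[0][0].size == 0:
            raise ValueError("dataset has no practice individual-learning trials")
        choices = np.stack([c for c, _ in pairs])
        rewards = np.stack([r for _, r in pairs])
        return choices, rewards

    def pointwise(self, natural: dict[str, np.ndarray], data) -> np.ndarray:
        choices, rewards = data
        return info_bonus_pointwise_grid(natural["alpha"], natural["beta"], natural["kappa"], choices, rewards)


def info_bonus_pointwise_grid(
    alpha: np.ndarray, beta: np.ndarray, kappa: np.ndarray, choices: np.ndarray, rewards: np.ndarray,
    engine: str = "auto",
) -> np.ndarray:
    """Vectorized per-trial log-likelihoods of the information-bonus model.

    Parameter arrays share shape ``(..., N)``; ``choices``/``rewards`` are
    (N, T).  Choice counts depend only on the data, so they are precomputed;
    the bonus kappa/N enters at decision time only.
    """
    alpha, beta, kappa = (np.asarray(x, dtype=float) for x in (alpha, beta, kappa))
    lead = beta.shape
    if engine == "auto":
        from . import _kernels

        if _kernels.HAVE_NUMBA and len(lead) >= 1:
            N_ = lead[-1]
            B_ = int(np.prod(lead[:-1], dtype=int)) if len(lead) > 1 else 1
            out = _kernels.info_bonus_pointwise(
                np.broadcast_to(alpha, lead).reshape(B_, N_),
                beta.reshape(B_, N_),
                np.broadcast_to(kappa, lead).reshape(B_, N_),
                np.atleast_2d(choices),
                np.atleast_2d(rewards),
            )
            return out.reshape(lead + (out.shape[-1],))
    N, T = choices.shape
    onehot = np.eye(3, dtype=np.int64)[choices]  # (N, T, 3)
    counts = 1 + np.concatenate(
        [np.zeros((N, 1, 3), dtype=np.int64), np.cumsum(onehot, axis=1)[:, :-1, :]], axis=1
    )  # counts before each trial
    q = np.full(lead + (3,), 0.5)
    out = np.empty(lead + (T,), dtype=float)
    idxN = np.arange(N)
    for t in range(T):
        vals = q + kappa[..., None] / counts[:, t, :]
        z = beta[..., None] * vals
        z = z - z.max(axis=-1, keepdims=True)
        e = np.exp(z)
        p = e[..., idxN, choices[:, t]] / e.sum(axis=-1)
        out[..., t] = np.log(np.maximum(p, 1e-300))
        qc = q[..., idxN, choices[:, t]]
        q[..., idxN, choices[:, t]] = qc + alpha * (rewards[:, t] - qc)
    return out


# -- densities ----------------------------------------------------------------


def _norm_logpdf(x, mu, sd):
    return -0.5 * ((x - mu) / sd) ** 2 - np.log(sd) - 0.5 * _LOG_2PI


def _halfcauchy_logpdf(x, scale):
    return np.where(x > 0, np.log(2.0 / (np.pi * scale)) - np.log1p((x / scale) ** 2), -np.inf)


def log_joint(
    model: HierModel,
    data,
    theta_raw: np.ndarray,
    mu: np.ndarray,
    sigma: np.ndarray,
) -> float:
    """Unnormalized log posterior of all raw parameters and hyperparameters.

    ``theta_raw`` is (N, P); ``mu`` and ``sigma`` are (P,).  With N = 0 only
    the hyperprior terms remain.
    """
    theta_raw = np.atleast_2d(np.asarray(theta_raw, dtype=float))
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("log_joint: sigma must be positive")
    total = float(np.sum(_norm_logpdf(mu, 0.0, MU_PRIOR_SD)))
    total += float(np.sum(_halfcauchy_logpdf(sigma, SIGMA_CAUCHY_SCALE)))
    if theta_raw.size:
        natural = _natural_dict(model, np.moveaxis(theta_raw, -1, 0))
        ll = float(model.pointwise(natural, data).sum())
        if not np.isfinite(ll):
            raise FloatingPointError("log_joint: non-finite likelihood term")
        total += ll
        total += float(np.sum(_norm_logpdf(theta_raw, mu, sigma)))
    if not np.isfinite(total):
        raise FloatingPointError("log_joint: non-finite prior term")
    return total


def _natural_dict(model: HierModel, theta_by_param: np.ndarray) -> dict[str, np.ndarray]:
    """theta_by_param: (P, ..., N) raw values -> {name: natural (..., N)}."""
    return {spec.name: to_natural(theta_by_param[i], spec.transform) for i, spec in enumerate(model.specs)}


# -- WAIC ---------------------------------------------------------------------


@dataclass(frozen=True)
class WAICResult:
    waic: float
    lppd: float
    p_waic: float


def waic(pointwise: np.ndarray) -> WAICResult:
    """WAIC from a (draws, trials) pointwise log-likelihood matrix."""
    ll = np.asarray(pointwise, dtype=float)
    if ll.ndim != 2:
        raise ValueError("pointwise log-likelihood must be 2-D (draws x trials)")
    D = ll.shape[0]
    if D < 2:
        raise ValueError("WAIC requires at least 2 posterior draws")
    m = ll.max(axis=0)
    lppd = float(np.sum(m + np.log(np.mean(np.exp(ll - m), axis=0))))
    p_waic = float(np.sum(np.var(ll, axis=0, ddof=1)))
    return WAICResult(waic=-2.0 * (lppd - p_waic), lppd=lppd, p_waic=p_waic)


# -- fit result ---------------------------------------------------------------


@dataclass
class FitResult:
    model_name: str
    param_names: tuple[str, ...]
    participant_ids: tuple[str, ...]
    theta_raw: np.ndarray  # (chains, draws, N, P)
    mu: np.ndarray  # (chains, draws, P)
    sigma: np.ndarray  # (chains, draws, P)
    participant_means: pd.DataFrame  # posterior means on the natural scale
    pointwise: np.ndarray  # (chains*draws, total trials)
    waic: WAICResult
    diagnostics: dict
    warnings: list[str] = field(default_factory=list)

    def to_inference_data(self):
        """Posterior draws as an arviz InferenceData (chain, draw, ...)."""
        import arviz as az

        posterior = {}
        for i, name in enumerate(self.param_names):
            posterior[f"mu_{name}"] = self.mu[:, :, i]
            posterior[f"sigma_{name}"] = self.sigma[:, :, i]
            posterior[f"{name}_raw"] = self.theta_raw[:, :, :, i]
        return az.from_dict(
            posterior=posterior,
            coords={"participant": list(self.participant_ids)},
            dims={f"{n}_raw": ["participant"] for n in self.param_names},
        )

    def save(self, path: str | Path) -> None:
        """Persist draws and metadata to an .npz with a dims manifest."""
        np.savez_compressed(
            path,
            theta_raw=self.theta_raw,
            mu=self.mu,
            sigma=self.sigma,
            pointwise=self.pointwise,
            participant_means=self.participant_means.to_numpy(),
            meta=np.array(
                [
                    _json.dumps(
                        {
                            "model_name": self.model_name,
                            "param_names": list(self.param_names),
                            "participant_ids": list(self.participant_ids),
                            "dims": {
                                "theta_raw": ["chain", "draw", "participant", "parameter"],
                                "mu": ["chain", "draw", "parameter"],
                                "sigma": ["chain", "draw", "parameter"],
                                "pointwise": ["sample", "trial"],
                            },
                            "waic": [self.waic.waic, self.waic.lppd, self.waic.p_waic],
                            "diagnostics": {k: float(v) for k, v in self.diagnostics.items()},
                            "warnings": self.warnings,
                        }
                    )
                ]
            ),
        )

    @classmethod
    def load(cls, path: str | Path) -> "FitResult":
        with np.load(path, allow_pickle=False) as z:
            meta = _json.loads(str(z["meta"][0]))
            means = pd.DataFrame(
                z["participant_means"], index=meta["participant_ids"], columns=meta["param_names"]
            )
            w = meta["waic"]
            return cls(
                model_name=meta["model_name"],
                param_names=tuple(meta["param_names"]),
                participant_ids=tuple(meta["participant_ids"]),
                theta_raw=z["theta_raw"],
                mu=z["mu"],
                sigma=z["sigma"],
                participant_means=means,
                pointwise=z["pointwise"],
                waic=WAICResult(*w),
                diagnostics=meta["diagnostics"],
                warnings=list(meta["warnings"]),
            )


# -- sampler ------------------------------------------------------------------


def fit_model(
    model: HierModel,
    dataset: StudyDataset,
    chains: int = 4,
    warmup: int = 1000,
    draws: int = 1000,
    seed: int = 0,
    target_accept: float = 0.44,
) -> FitResult:
    """Fit any :class:`HierModel` hierarchically by blocked adaptive MCMC."""
    data = model.prepare(dataset)
    P = len(model.specs)
    N = len(dataset.participants)
    if N < 1:
        raise ValueError("fit requires at least one participant")
    C = chains
    rng = np.random.default_rng(seed)

    theta = 0.5 * rng.standard_normal((C, N, P))
    mu = 0.3 * rng.standard_normal((C, P))
    sigma = np.exp(0.1 * rng.standard_normal((C, P)))
    s_theta = np.full((C, N, P), 0.5)
    s_sigma = np.full((C, P), 0.5)
    s_asis = np.full((C, P), 0.3)

    def loglik(th: np.ndarray) -> np.ndarray:
        # th: (C, N, P) -> summed log-likelihood per (chain, participant)
        natural = _natural_dict(model, np.moveaxis(th, -1, 0))
        return model.pointwise(natural, data).sum(axis=-1)

    ll_cur = loglik(theta)
    acc_theta_total = 0.0
    acc_sigma_total = 0.0

    theta_draws = np.empty((C, draws, N, P))
    mu_draws = np.empty((C, draws, P))
    sigma_draws = np.empty((C, draws, P))

    total_iters = warmup + draws
    acc_theta_mean = 0.0
    for it in range(total_iters):
        gamma = min(0.25, 4.0 / (it + 1) ** 0.6) if it < warmup else 0.0
        # 1. participant-level raw parameters: componentwise random-walk MH
        #    (one parameter at a time, all chains/participants in parallel)
        acc_theta_mean = 0.0
        for p in range(P):
            prop = theta.copy()
            prop[:, :, p] = theta[:, :, p] + rng.standard_normal((C, N)) * s_theta[:, :, p]
            ll_prop = loglik(prop)
            pri_cur = _norm_logpdf(theta[:, :, p], mu[:, None, p], sigma[:, None, p])
            pri_prop = _norm_logpdf(prop[:, :, p], mu[:, None, p], sigma[:, None, p])
            logr = (ll_prop + pri_prop) - (ll_cur + pri_cur)
            acc = np.log(rng.random((C, N))) < logr
            theta = np.where(acc[..., None], prop, theta)
            ll_cur = np.where(acc, ll_prop, ll_cur)
            acc_theta_mean += acc.mean() / P
            if it < warmup:
                s_theta[:, :, p] *= np.exp(gamma * (acc.astype(float) - target_accept))

        # 2. population means: conjugate Gibbs draw
        prec = 1.0 / MU_PRIOR_SD**2 + N / sigma**2
        mean = (theta.sum(axis=1) / sigma**2) / prec
        mu = mean + rng.standard_normal((C, P)) / np.sqrt(prec)

        # 3. population sds: MH on log sigma (Jacobian term included)
        log_sig_prop = np.log(sigma) + rng.standard_normal((C, P)) * s_sigma
        sig_prop = np.exp(log_sig_prop)

        def sig_logpost(sig):
            like = _norm_logpdf(theta, mu[:, None, :], sig[:, None, :]).sum(axis=1)
            return like + _halfcauchy_logpdf(sig, SIGMA_CAUCHY_SCALE) + np.log(sig)

        logr_s = sig_logpost(sig_prop) - sig_logpost(sigma)
        acc_s = np.log(rng.random((C, P))) < logr_s
        sigma = np.where(acc_s, sig_prop, sigma)

        # 4. non-centered interleaving, one parameter at a time: move
        #    (mu_p, sigma_p) with eta_p = (theta_p - mu_p)/sigma_p fixed
        for p in range(P):
            eta_p = (theta[:, :, p] - mu[:, None, p]) / sigma[:, None, p]
            mu_prop_p = mu[:, p] + rng.standard_normal(C) * s_asis[:, p]
            lsig_prop_p = np.log(sigma[:, p]) + rng.standard_normal(C) * s_asis[:, p]
            sig_prop_p = np.exp(lsig_prop_p)
            theta_prop = theta.copy()
            theta_prop[:, :, p] = mu_prop_p[:, None] + sig_prop_p[:, None] * eta_p
            ll_prop2 = loglik(theta_prop)
            logr_a = (
                ll_prop2.sum(axis=1)
                - ll_cur.sum(axis=1)
                + _norm_logpdf(mu_prop_p, 0.0, MU_PRIOR_SD) - _norm_logpdf(mu[:, p], 0.0, MU_PRIOR_SD)
                + _halfcauchy_logpdf(sig_prop_p, SIGMA_CAUCHY_SCALE) - _halfcauchy_logpdf(sigma[:, p], SIGMA_CAUCHY_SCALE)
                + lsig_prop_p - np.log(sigma[:, p])  # Jacobian of the log-scale proposal
            )
            acc_a = np.log(rng.random(C)) < logr_a
            mu[acc_a, p] = mu_prop_p[acc_a]
            sigma[acc_a, p] = sig_prop_p[acc_a]
            theta = np.where(acc_a[:, None, None], theta_prop, theta)
            ll_cur = np.where(acc_a[:, None], ll_prop2, ll_cur)
            if it < warmup:
                s_asis[:, p] *= np.exp(gamma * (acc_a.astype(float) - 0.35))

        if it < warmup:
            s_sigma *= np.exp(gamma * (acc_s.astype(float) - 0.44))
        else:
            d = it - warmup
            theta_draws[:, d] = theta
            mu_draws[:, d] = mu
            sigma_draws[:, d] = sigma
            acc_theta_total += acc_theta_mean
            acc_sigma_total += acc_s.mean()

    # posterior means on the natural scale, per participant
    nat_draws = _natural_dict(model, np.moveaxis(theta_draws, -1, 0))  # name -> (C, D, N)
    means = pd.DataFrame(
        {name: nat_draws[name].mean(axis=(0, 1)) for name in nat_draws},
        index=[p.participant_id for p in dataset.participants],
    )

    # pointwise log-likelihood at every retained draw (for WAIC)
    flat = theta_draws.reshape(C * draws, N, P)
    nat_flat = _natural_dict(model, np.moveaxis(flat, -1, 0))
    pw = model.pointwise(nat_flat, data)  # (C*D, N, T)
    pointwise = pw.reshape(C * draws, -1)

    diagnostics, warn = _diagnose(model, theta_draws, mu_draws, sigma_draws)
    diagnostics["accept_theta"] = acc_theta_total / draws
    diagnostics["accept_sigma"] = acc_sigma_total / draws
    diagnostics["divergences"] = 0  # random-walk kernel: divergence-free by construction

    return FitResult(
        model_name=model.name,
        param_names=tuple(s.name for s in model.specs),
        participant_ids=tuple(p.participant_id for p in dataset.participants),
        theta_raw=theta_draws,
        mu=mu_draws,
        sigma=sigma_draws,
        participant_means=means,
        pointwise=pointwise,
        waic=waic(pointwise),
        diagnostics=diagnostics,
        warnings=warn,
    )


def _diagnose(model, theta_draws, mu_draws, sigma_draws):
    import arviz as az

    rhats = []
    esss = []
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        for i in range(mu_draws.shape[-1]):
            for arr in (mu_draws[:, :, i], sigma_draws[:, :, i]):
                rhats.append(float(az.rhat(arr.copy())))
                esss.append(float(az.ess(arr.copy())))
    diagnostics = {"max_rhat": float(np.nanmax(rhats)), "min_ess": float(np.nanmin(esss))}
    warn = []
    if diagnostics["max_rhat"] > RHAT_THRESHOLD:
        warn.append(
            f"non-convergence: split R-hat {diagnostics['max_rhat']:.3f} exceeds {RHAT_THRESHOLD} "
            f"on a hyperparameter of model {model.name!r}"
        )
    return diagnostics, warn


def fit_hierarchical(
    dataset: StudyDataset,
    kind: str,
    chains: int = 4,
    warmup: int = 1000,
    draws: int = 1000,
    seed: int = 0,
) -> FitResult:
    """Fit one of the observational-learning models to a study's
    observational-phase choices."""
    return fit_model(ObsLearningModel(kind), dataset, chains=chains, warmup=warmup, draws=draws, seed=seed)


def fit_individual(
    dataset: StudyDataset,
    chains: int = 4,
    warmup: int = 1000,
    draws: int = 1000,
    seed: int = 0,
) -> FitResult:
    """Fit the information-bonus model to practice individual-learning choices."""
    return fit_model(InfoBonusModel(), dataset, chains=chains, warmup=warmup, draws=draws, seed=seed)
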