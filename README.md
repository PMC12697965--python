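# obslearn

Computational analysis of **partner selection in observational reinforcement
learning**: who do people choose to learn from when they can watch someone
else play a bandit, and how does that choice relate to their own learning
style?

The package targets researchers in computational cognitive modelling. It
implements, as a tested pipeline on synthetic data:

* a three-armed Bernoulli bandit task (reward probabilities 0.25 / 0.50 /
  0.75) with simulated Q-learning partners that differ only in decision
  noise — a **high-noise** partner (softmax inverse temperature β = 1.5) and
  a **low-noise** partner (β = 20), both with learning rate α = 0.3;
* three observational-learning models of the participant; the **Full model**
  tracks, per option X,

  * action values learned vicariously from the partner's outcomes
    (V_X ← V_X + α_V (R − V_X)), and
  * imitation tendencies pushed toward the partner's choices
    (A_chosen ← A_chosen + α_A (1 − A_chosen),
    A_unchosen ← A_unchosen + α_A (0 − A_unchosen)),

  combined as Q_X = (1 − w_A)·V_X + w_A·A_X and passed through a softmax
  with inverse temperature β. Setting w_A = 1 gives the nested **Action
  Learning** model, w_A = 0 the **Reward Learning** model;
* **hierarchical Bayesian fitting** of these models: raw parameters per
  participant are Normal(μ, σ²) with logistic/exponential transforms to
  their domains, hyperpriors μ ~ N(0, 1) and σ ~ Half-Cauchy(0, 3), sampled
  by a blocked adaptive MCMC scheme, compared by **WAIC**;
* **model- and parameter-recovery** studies (confusion matrices,
  true-vs-estimated correlations, preference-stratified bias);
* block-level **partner metrics** — performance (total reward),
  predictability (log-likelihood of the partner's choices under the
  observer's own fitted decision model, an information-bonus RL model with
  bonus κ/N_X), and information gain (total bonus reduction the partner's
  exploration induces);
* mixed-effects logistic **regressions**: partner-selection models,
  option-wise trial-level learning-style GLMMs with inverse-variance pooled
  coefficients, marginal effects, Cohen's d contrasts, chance-level t-tests
  and a bootstrap power analysis;
* **posterior predictive checks** regenerating learning curves and GLMM
  effects from fitted parameters.

No human data ships with the package: the `synthetic_data` module generates
complete studies with the task's exact structure (60-trial practice phases,
four main blocks of two 30-trial passive demonstrations + a 60-trial
observational phase, partner assignment P(low-noise) = 0.7, parameters drawn
Beta(1.1, 1.1) and U(0, 30)), so every analysis runs end to end from a seed.

## Worked example

```python
from obslearn.synthetic_data import StudyDesign, generate_study
from obslearn.hier_fit import fit_hierarchical
from obslearn.regressions import build_selection_design, fit_mixed_logistic

design = StudyDesign(n_participants=20, n_blocks=4, seed=7)
dataset, truth = generate_study(design, "full")

for kind in ("full", "action_only", "reward_only"):
    fit = fit_hierarchical(dataset, kind, chains=4, warmup=400, draws=400, seed=8)
    print(f"{kind:12s} WAIC = {fit.waic.waic:8.1f}")

sel = build_selection_design(dataset, "model1")
e = fit_mixed_logistic(sel, "Y", ["X1"]).effect("X1")
print(f"noise effect on selection: b = {e.estimate:.2f} +/- {e.se:.2f}, "
      f"t({e.df}) = {e.stat:.2f}, p = {e.p:.4f}")
```

Output:

```
full         WAIC =   2651.6
action_only  WAIC =   3930.9
reward_only  WAIC =   5429.9
noise effect on selection: b = -0.58 +/- 0.26, t(20) = -2.25, p = 0.0360
```

The Full model wins the WAIC comparison on data it generated (lower is
better), and the selection regression recovers a negative noise-level
coefficient: these synthetic participants — whose partner assignment is
70% low-noise — are less likely to pick the high-noise partner. X1 codes
the high-noise partner's screen side (+1 left), Y codes choosing the left
partner, so b < 0 means low-noise partners are preferred.

## Command line

```bash
obslearn simulate --out study.csv --truth truth.csv --model full --seed 0
obslearn fit --data study.csv --model full --out fit_full.npz
obslearn waic fit_full.npz fit_action_only.npz fit_reward_only.npz
obslearn recover --mode model --reps 5 --out confusion.csv
obslearn run-all --config src/obslearn/configs/reduced.yaml
```

`run-all` executes the whole pipeline (simulate → fit ×3 → WAIC → recovery
→ partner metrics → regressions → PPC) and writes a content-hashed
manifest. The bundled `reduced.yaml` runs in minutes; `paper.yaml` holds
the full-scale settings (74 participants, 4×1000/1000 MCMC, 40 recovery
replicates, 500 PPC replicates).

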