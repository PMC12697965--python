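# Methods

## Task and agents

The environment is a three-armed bandit with independent Bernoulli rewards
at probabilities (0.25, 0.50, 0.75); the mapping of probabilities to
stimuli/screen positions is randomized in the real task and is not modelled
— options are bare indices 0–2 and the "correct" option is the argmax
(ties broken by lowest index; with the default structure ties cannot
occur).

Partners are standard Q-learning agents: softmax choice over Q with inverse
temperature β, delta-rule update Q_c ← Q_c + α(R − Q_c). The two candidate
partners differ only in β (high-noise 1.5, low-noise 20.0; practice partner
7.0; all α = 0.3). Partner Q values initialize at 0.5, the midpoint of the
{0,1} reward scale and the same convention as the learner's V below; the
initialization is a package choice, as the agent description leaves it
open. Lower β means noisier, more exploratory behavior; because exploration
is costly in this stationary task, β = 20 partners reliably out-earn β =
1.5 partners — the structural fact behind the performance/noise confound
the selection analyses decompose.

## Observational-learning models

The Full model holds per-option action values V (initialized 1/2) and
action tendencies A (initialized 1/3). On each trial the partner acts
first; the learner then updates

* V_c ← V_c + α_V (R − V_c) for the partner's choice c and outcome R
  (vicarious reward learning), and
* A ← (1 − α_A) A + α_A · onehot(c) (imitation). This is an affine
  contraction toward a probability vector, so ΣA = 1 is conserved exactly
  and each A_X stays in [0,1].

The participant's own choice is then evaluated (or sampled) from
softmax(β Q) with Q = (1 − w_A) V + w_A A. The participant's own outcome is
withheld by the task and never updates state. State resets at every block
boundary because stimuli are re-randomized across blocks. The Action
Learning and Reward Learning models are the nested cases w_A = 1 (softmax
over A) and w_A = 0 (softmax over V); the nesting identities are enforced
by property tests to 1e-10.

Within-trial ordering is a substantive choice: the likelihood of trial t's
participant choice conditions on the partner's event of the same trial,
because the task screen shows the partner's outcome before the participant
responds. Both update rules touch disjoint state, so their order within a
trial is irrelevant.

## Parameters

| parameter | domain | role |
|---|---|---|
| α_V | [0,1] | vicarious reward-learning rate |
| α_A | [0,1] | imitation (action-tendency) rate |
| w_A | [0,1] | imitation weight mixing A against V |
| β | ≥ 0 | softmax inverse temperature (decision noise⁻¹) |
| α, β, κ | [0,1], ≥0, [0,1] | information-bonus model of individual learning |

The information-bonus model adds κ/N_X to option X's value at decision
time, where N_X counts X's past choices starting from a pseudo-count of 1
(the only finite convention compatible with the bonus-decrement formula
κ(1/N_X − 1/(N_X+1))). The bonus affects choice only; the delta rule
updates the raw values. Information gain of a demonstration telescopes to
κ · Σ_X (1 − 1/(c_X + 1)) for per-option counts c_X, which the
implementation must match to 1e-12.

## Synthetic studies

`synthetic_data.generate_study` emulates the full protocol per participant:
a 60-trial practice individual-learning phase (the participant acting as a
Q-learner with their own α_V and β — a generative stand-in for real
practice behavior that preserves the participant-specific decision
process), a 60-trial practice observational phase with the β = 7 partner,
then four main blocks: two 30-trial passive demonstrations (one partner per
noise condition, presentation order and screen side counterbalanced within
participant), an exogenous partner selection (low-noise with probability
0.7, matching the empirically observed selection distribution — selection
is treated as exogenous, not generated from a selection model), and a
60-trial observational phase with the selected partner. Learner parameters
are drawn α_V, α_A, w_A ~ Beta(1.1, 1.1) and β ~ U(0, 30).

Each participant consumes a dedicated random stream spawned from the master
seed (`SeedSequence(seed, spawn_key=(i,))`), so enlarging a study never
perturbs existing participants, and identical (design, seed) pairs yield
byte-identical CSVs.

What the generator does **not** emulate: reaction times, attention or
memory limits, stimulus/position effects, within-session drift, or any
dependence of selection on the observed demonstrations. Passing tests
therefore show that the pipeline's estimators and codings behave correctly
under the stated generative assumptions — not that those assumptions hold
in human data.

## Hierarchical fitting

Raw parameters are unconstrained: unit-interval parameters map through the
logistic, β through exp. Raw parameters are Normal(μ_θ, σ_θ²) across
participants with hyperpriors μ_θ ~ N(0, 1) and σ_θ ~ Half-Cauchy(0, 3)
(the positive half of a Cauchy with scale 3).

The sampler is a blocked adaptive Metropolis-within-Gibbs scheme,
vectorized across chains and participants:

1. componentwise random-walk Metropolis on each participant's raw
   parameters (participants are conditionally independent given the
   hyperparameters, so all update in parallel; per-parameter proposal
   scales adapt toward 44% acceptance);
2. exact conjugate Gibbs draws for the population means;
3. log-scale Metropolis for the population SDs;
4. an ancillarity–sufficiency interleaving step per parameter: a joint
   (μ_p, σ_p) move holding the standardized effects η = (θ − μ)/σ fixed,
   which breaks the funnel coupling between σ and the participant level.

Adaptation runs during warmup only, so retained draws come from a fixed
kernel; a fixed seed reproduces draws exactly. The likelihood is evaluated
by a numba-compiled kernel (a pure-numpy path with identical output to
1e-12 serves as the reference and fallback). Convergence is summarized by
split R-hat and ESS (arviz) on all hyperparameters; any R-hat above 1.05
attaches a warning to the result rather than raising, and the random-walk
kernel has no divergences by construction. Defaults are 4 chains ×
1000 warmup + 1000 draws; desk-scale validation runs use 200/200, where
hyperparameter R-hats around 1.1–1.5 are common and are reported honestly —
the recovery quantities (WAIC winners, posterior-mean correlations) are
robust to this, which the validation battery demonstrates directly.

WAIC uses per-trial pointwise log-likelihoods at every retained draw:
lppd = Σ_t log mean_d exp(ll_dt), p_waic = Σ_t var_d(ll_dt) with the
sample-variance (ddof = 1) convention of Stan/loo; arviz uses the
population variance, and the cross-check test converts between the two by
the exact factor S/(S−1). Per-participant (instead of per-trial) pointwise
terms would be a one-line change in the adapter; per-trial is the standard
construction and the default.

## Partner metrics and regressions

Performance is the partner's total reward over the 30 passive trials.
Predictability is the log-likelihood of the partner's choice sequence under
the observer's information-bonus model (posterior means from the
hierarchical fit to the observer's practice individual-learning data, with
the same priors and transforms as the main fit; κ uses the logistic
transform). The observer's model state updates from the partner's choices
*and* rewards — the observer sees both. Information gain uses the
observer's κ.

Selection regressions code Y = 1 if the left partner was chosen, X1 = +1 if
the high-noise partner was on the left, X2 = +1 if the left partner was
demonstrated first. The factor model replaces X1 with right-minus-left
difference scores of the three metrics, z-standardized across all
participant-blocks pooled. The orientation convention (right − left against
a left-choice outcome) fixes coefficient signs; tests assert the
antisymmetry of the differences rather than any particular sign.

Learning-style GLMMs are fit option-wise (one mixed logistic per option,
outcome = participant chose X) with C = ±1 for the partner's same-trial
choice, R ∈ {+1, −1, 0} for the partner's outcome relative to X, and a
moderator: the participant's high-noise preference P ∈ {0, .25, .5, .75, 1}
(entered uncentered, so main effects are simple slopes at P = 0 and
marginal effects are reported at the five observed levels) or the block's
partner noise D = ±1 (within-participant version, restricted to
participants who experienced both partner types). Coefficients pool across
the three option models by inverse-variance weighting: b = Σw_k b_k / Σw_k,
SE = √(1/Σw_k), w_k = 1/SE_k².

Mixed models are estimated by statsmodels' variational-Bayes binomial
mixed GLM (by-participant random intercepts + slopes); degenerate or failed
mixed fits fall back to a fixed-effects GLM with cluster-robust SEs,
flagged in the output. The VB posterior covariance is mean-field
(diagonal), so marginal-effect SEs omit the main×interaction covariance
term under that engine; the GLM engine provides the full covariance.
Coefficient tests are two-tailed t-tests with df = number of participants —
a reporting convention, not a derived quantity. The bootstrap power
analysis simulates from the fitted Model 1 (fixed effects plus Normal
random effects at their estimated SDs), refits, and counts p < α.

## Recovery and posterior predictive checks

Model recovery generates studies from each candidate model, fits all three,
and tabulates WAIC winners into a confusion matrix; parameter recovery
correlates posterior means with generating values per replicate. Replicate
seeds derive deterministically from the master seed. Preference groups are
majority-based (strictly more high- than low-noise blocks → high-noise
group; exact splits discarded), which reduces to the
"more than two of four blocks" rule at the standard block count and remains
defined at reduced block counts. Stratified recovery post-stratifies the
joint fit rather than refitting within groups; groups under 3 participants
have correlations omitted with a warning. "Estimated parameter" means the
posterior mean on the natural scale (mean vs median being an open
convention).

PPCs regenerate each participant's blocks with fresh partner streams drawn
from the recorded noise conditions (conditions are fixed; realizations are
not) and simulate choices from posterior-mean parameters (a config switch
draws one posterior sample per replicate instead). Learning curves and
pooled GLMM effects are summarized across replicates by mean and SD.

## Problem sizes

Desk-scale validation uses 10 participants × 2 blocks with 4 × 200/200
MCMC, 5 recovery replicates per generating model, 20-replicate regression
direction checks, 50 PPC replicates, and a 55-participant study for the
regression battery; full-scale settings (74 participants, 4 blocks,
4 × 1000/1000, 40 replicates, 500 PPC replicates) live in
`configs/paper.yaml`. These desk-scale sizes are the package's validation
conditions of choice; all are overridable per run.

## Known limitations

* The random-walk sampler needs longer chains than gradient-based samplers
  for tight hyperparameter inference; short-chain hyperparameter R-hats
  carry warnings (see above).
* β is weakly identified above ~15 (behavior saturates toward argmax), so
  recovery correlations for β on the natural scale are noisy by
  construction.
* No time-varying imitation weight: the weight w_A is constant within
  participant.
* Selection is exogenous in the generator, so selection-model coefficients
  on synthetic data reflect the assignment distribution, not a
  decision process.
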