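# Desk-scale settings: the whole pipeline in minutes.
seed: 0
outdir: obslearn_out
model: full
design:
  n_participants: 10
  n_blocks: 2
  passive_trials: 30
  observational_trials: 60
  practice_trials: 60
  p_low_noise: 0.7
  reward_probs: [0.25, 0.50, 0.75]
fit:
  chains: 4
  warmup: 200
  draws: 200
recovery:
  n_reps: 5
  reduced_scale: true
regress:
  engine: auto
ppc:
  n_reps: 20
  refit_glmm: true
  glmm_engine: glm
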