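# Full-scale study settings.
seed: 0
outdir: obslearn_out
model: full
design:
  n_participants: 74
  n_blocks: 4
  passive_trials: 30
  observational_trials: 60
  practice_trials: 60
  p_low_noise: 0.7
  reward_probs: [0.25, 0.50, 0.75]
fit:
  chains: 4
  warmup: 1000
  draws: 1000
recovery:
  n_reps: 40
  reduced_scale: false
regress:
  engine: auto
ppc:
  n_reps: 500
  refit_glmm: true
  glmm_engine: glm
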