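# Default cohort run: 31 subjects, full 800-trial task, a-priori effect
# sizes and noise levels.  Every entry is optional except `seed`; unknown
# keys are rejected by `validate-config`.
seed: 0
n_subjects: 31

# Task design overrides (defaults shown commented out).
task: {}
#   n_blocks: 8
#   trials_per_block: 100
#   frac_nogo_per_block: 0.25
#   frac_salient_per_block: 0.10

# Effect-structure overrides: target_correlations, covariate_correlations,
# noise_scale, sex_male_prob.
effects: {}

preprocess:
  l_freq: 0.1
  h_freq: 30.0

stats:
  alpha: 0.05
  m_per_component: 4

sfreq: 200.0
smooth_hz: null
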