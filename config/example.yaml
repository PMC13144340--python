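# End-to-end run on a simulated cohort: framesync run --config config/example.yaml
seed: 7
out_dir: scratch/example_run
sim:
  n_participants: 10
  grid_dims: [6, 6, 6]
  n_stimuli: 6
  segment_duration_s: 60.0
  kappa_by_frame: {neutral: 0.8, threat: 0.5, blame: 0.4}
  gamma_proximity: {neutral: 0.2, threat: 0.5, blame: 0.8}
  seed: 7
n_exclude_volumes: 8
grouping: frame
baseline: none
contrasts:
  - [neutral, threat]
  - [neutral, blame]
n_permutations: 500
fwe: across
tfce: {E: 0.5, H: 2.0, connectivity: 6}
proximity_variables: [pvv_attitude]
proximity_conditions: [threat, blame]
survey: {n_participants: 1800, seed: 7}
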