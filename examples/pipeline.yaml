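# Example configuration for `ncreann run-all --config examples/pipeline.yaml out/`
# Only keys that deviate from the defaults need to be listed.

seed: 0
srate: 256.0
epoch_window: [-2.0, 2.0]
analysis_window: [-1.0, 1.0]

bands:
  theta: [4.0, 7.0]
  alpha: [8.0, 12.0]
  beta: [12.0, 25.0]

sensor_study:
  n_subjects: 8
  n_trials: 8
  n_channels: 32
  effect_size_d: {theta: 1.0}   # planted band-power contrast (A > B)
  neighbor_distance: 1.2        # channel adjacency threshold (position units)

n_perm: 500                     # cluster-test sign-flip draws

source_study:
  n_subjects: 4
  M: 3                          # planted source count / network nodes
  n_trials: 10
  n_samples: 128
  grid_shape: [6, 6, 6]
  n_sensor_channels: 24
  sensor_noise_sd: 0.02
  effect_size_d: 0.5            # per-edge coupling contrast (A > B)
  behavior_r: 0.29              # planted brain-behavior correlation

ncreann:
  order: 2                      # lag order p
  hidden: 8
  folds: 3
  max_epochs: 60
  patience: 10

contrast_direction: greater     # one-sided alternative: A > B
display:
  scale: 100.0                  # figure values scaled x100
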