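# Example steamref run configuration.
# Defaults reproduce the published postmortem protocol; only deviations
# need to be listed.  Every subcommand reads its own section.
seed: 7

protocol:
  Delta_list_ms: [70, 100, 150, 200, 250, 300, 350, 400]
  delta_ms: 2.22
  nominal_b: 3.5          # ms·um^-2
  te_ms: 16.0
  n_directions: 30
  reference_mode: fixed_b0
  b0_at_delta_max: 0.631  # ms·um^-2 (three-axis crushers)
  n_axes: 3

model:                    # tissue model for `curves` / `contours`
  type: biexp
  f_s: 0.3
  D_s: 0.2
  D_f: 1.0

phantom:                  # for `simulate`
  shape: [32, 24, 5]
  voxel_size_mm: 0.4
  snr: 30.0               # Rician, referred to the WM amplitude at the shortest Delta
  sigma: null

curves:
  b0_fractions: [0.0, 0.1, 0.2, 0.3]

contours:
  b_grid: [0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0]
  Delta_grid_ms: [70, 100, 150, 200, 250, 300, 350, 400]
  b0_fraction: 0.2

seqcheck:
  q_crusher: 0.046        # um^-1
  q_slice: 0.046

validate_mc:
  n_walkers: 100000
  q_values: [0.02, 0.05, 0.1]
  Delta_values_ms: [10, 50, 200, 500]
  r_um: 5.0
  D: 2.0
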