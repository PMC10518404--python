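# Full-scale configuration mirroring the clinical protocol:
# 256x256 grids, six depths, lr 5e-5 for up to 200 epochs with early stopping.
phantom:
  grid_size: 256
  myo_radius_range: [32, 52]
  wall_thickness_range: [16, 32]
  center_jitter: 16.0
  noise_sigma: 0.05
  lesion_probability: 0.3
  hard_case_fraction: 0.15
  seed: 0
cohort:
  n_patients: 200
  slices_per_patient: 3
  fractions: [0.85, 0.075, 0.075]
ensemble:
  depths: [1, 2, 3, 4, 5, 6]
  base_filters: 16
  input_size: 256
training:
  learning_rate: 5.0e-5
  max_epochs: 200
  early_stop_patience: 10
  batch_size: 8
  seed: 0
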