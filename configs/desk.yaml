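# Desk-scale configuration: 64x64 phantoms, depths 1-3, short training.
phantom:
  grid_size: 64
  noise_sigma: 0.05
  lesion_probability: 0.3
  hard_case_fraction: 0.15
  seed: 0
cohort:
  n_patients: 60
  slices_per_patient: 2
  fractions: [0.85, 0.075, 0.075]
ensemble:
  depths: [1, 2, 3]
  base_filters: 8
  input_size: 64
training:
  learning_rate: 1.0e-3
  max_epochs: 15
  early_stop_patience: 6
  batch_size: 8
  seed: 0
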