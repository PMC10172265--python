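# Example pipeline configuration for `spinecreep train --config examples/config.yaml`.
# Omitted keys fall back to the shipped defaults (full default dataset,
# desk-scale surrogate). Generator keys mirror GeneratorConfig fields.
generator:
  n_specimens: 3
  n_train: 116
  n_validation: 9
model:
  hidden_units: [32, 64]
  learning_rate: 3.0e-3
  lr_decay: 0.9995
  batch_size: 16
  max_epochs: 3000
  target_loss: 5.0e-4
  patience: 50
  # reference: true   # switch to the full-scale 6-layer configuration
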