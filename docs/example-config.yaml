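# Example run configuration for the cuffgraph CLI.
#
# Any section may be omitted; omitted keys fall back to the package
# defaults shown in the library dataclasses.  Command-line flags override
# file values.  Unknown keys are rejected with the failing key path.

# top-level seed: used for any section that takes a seed and does not set
# its own
seed: 1

graph:
  metric: geodesic      # geodesic | euclidean | random
  k: 5                  # nearest neighbours per node
  sigma: 2.0            # Gaussian distance-decay scale
  # seed: 1             # used only for metric: random

model:
  encoder: lstm         # lstm | cnn1d (encoder ablation)
  encoder_units: 256
  edgeconv_units: 32
  gconv_units: 128
  dense_units: [64]
  dropout: 0.2
  l2: 5.0e-3
  node_feature: last    # last | mean hidden state as node feature

train:
  learning_rate: 1.0e-3
  batch_size: 1024      # capped at the training-set size
  max_epochs: 60
  patience: 8
  augment_fraction: 0.05   # Gaussian-noise augmentation, sd as fraction of RMS
  validation_subjects: []  # subjects excluded from LOSO aggregate means

synth:
  n_subjects: 4
  n_per_class: 40
  n_timesamples: 100
  noise_sd: 0.1
  subject_gain_sd: 0.2
  subject_jitter_sd: 2.0
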