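n_subjects: 40
samples_per_subject: 2
n_features: 60
n_blocks: 6
within_block_corr: 0.7
base_abundance_sd: 1.0
depth: 4000
sparsity_target: 0.3
unclassifiable_fraction: 0.3
block_effects:
  HFD_TRF: {B1: 1.5, B2: -1.5}
rhythmic_blocks: {}
phenotypes:
  fasting_glucose:
    intercept: 8.0
    beta: {B1: -30.0}
    noise_sd: 0.5
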