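censoring_rate: 0.1
clinical_path: ''
cnn:
  batch_size: 4
  dense_width: 32
  dropout_rate: 0.5
  epochs: 40
  filters:
  - 8
  - 16
  kernel_sizes:
  - - 1
    - 3
  - - 1
    - 3
  learning_rate: 0.001
  n_conv_layers: 2
  n_ensemble: 4
  pool_sizes:
  - - 1
    - 2
  - - 1
    - 1
  seed: 0
  validation_split: 0.2
  weight_decay: 0.001
cox:
  alpha: 0.01
  include_censored_short: true
  mode: multivariate-per-pathway
  omics: EXP
exclusion_path: ''
genes_per_pathway:
- 10
- 30
gmt_path: ''
k_folds: 3
mode: fold-safe
n_omics: 3
n_pathways: 20
n_pcs: 2
n_samples_per_class:
- 30
- 45
n_short_censored: 10
noise_sd: 1.0
omics_orientation: samples-as-rows
omics_paths: {}
planted:
- - 4
  - 0
  - 2.5
- - 4
  - 1
  - 2.5
- - 4
  - 2
  - 2.5
seed: 5
shap:
  n_baselines: 25
  n_path_samples: 2
  noise_sd: null
  seed: 0
source: synthetic
survival_betas:
  0: 0.8
threshold_years: 2.0
time_unit: years
top_k: 5
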