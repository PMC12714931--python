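seed: 0
rnaseq:
  n_genes: 300
  n_up: 30
  n_down: 30
  n_control: 5
  n_post: 5
  baseline_mean: 100.0
  sigma: 15.0
  up_mean_control: 100.0
  up_mean_post: 300.0
  down_mean_control: 100.0
  down_mean_post: 30.0
  marker_mean_control: 50.0
  marker_mean_post: 200.0
  markers:
    B:
    - CD19
    - MS4A1
    T:
    - CD3D
    - CD8A
    - CD4
    Ig:
    - IGHG1
    - IGHM
    - PRDM1
    Tmem:
    - IL7R
    - CCR7
    TC:
    - GZMB
    - PRF1
    EP:
    - EPCAM
    - KRT18
diffexpr:
  fdr: 0.05
compartments:
- name: Ig
  markers:
  - IGHG1
  - IGHM
  - PRDM1
  delta_auc: 1.4
- name: T
  markers:
  - CD3D
  - CD8A
  - CD4
  delta_auc: 1.2
- name: Tmem
  markers:
  - IL7R
  - CCR7
  delta_auc: 1.1
- name: TC
  markers:
  - GZMB
  - PRF1
  delta_auc: 0.9
- name: B
  markers:
  - CD19
  - MS4A1
  delta_auc: 0.8
- name: EP
  markers:
  - EPCAM
  - KRT18
  delta_auc: 0.6
risk:
  bootstrap_B: 1000
  ci_level: 0.95
lnp:
  n: 100
  noise_sd: 0.1
  scheme: lhs
surrogate:
  train_frac: 0.8
  n_trees: 500
  min_leaf: 2
  max_depth: null
  bootstrap_B: 500
ga:
  pop_size: 50
  generations: 100
  p_crossover: 0.8
  p_mutation: 0.2
  tournament_size: 3
  elitism: 1
  top_k: 10
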