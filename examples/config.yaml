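# Desk-scale end-to-end configuration on synthetic data.
# Replace the `synthetic` block with an `inputs` block (expression/cls/gmt/
# network paths) to run on real files.
seed: 1
log_level: INFO

synthetic:
  n_genes: 400
  n_replicates_per_group: 3
  n_sets: 10
  set_size_range: [15, 15]
  set_overlap_fraction: 0.0
  n_planted_de_sets: 3
  planted_de_set_names: [S0000, S0001, S0002]
  effect_size: 3.0
  noise_sd: 1.0
  background_edge_prob: 0.002
  planted_links:
    - [S0000, S0001, 10]

cluster:
  linkage: complete
  metric: euclidean

gsea:
  min_set_size: 10
  max_set_size: 500
  n_permutations: 2000   # publication default: 5000
  weight_exponent: 1.0
  q_threshold: 0.01

network:
  score_min: 500

bpn:
  burn_in_steps: 20000     # publication scale: 10000000
  mcmc_steps: 200000       # publication scale: 100000000
  thinning: 10
  link_penalty: 2.0
  inverse_temperature: 1.0
  probability_threshold: 0.45
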