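# Demo pipeline: synthetic 400 genes x 120 samples with five planted modules.
output_dir: coexnet_out/demo
seed: 3
simulate:
  n_samples: 120
  module_sizes: [80, 70, 60, 50, 40]
  n_background: 100
  factor_strength: 1.0
  noise_sd: 0.33
  loading_spread: 0.5
  n_chromosomes: 5
beta: 6
stability_iterations: 200
top_n_edges: 10
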