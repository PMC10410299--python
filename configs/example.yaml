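# pipeline configuration: simulation mode with the analysis defaults
outdir: results/pipeline
seed: 42
deg_fdr: 0.01
enrich_fdr: 0.05
simulation:
  n_genes: 1000
  n_replicates: 3
  dispersion: 0.05
  mean_lib_size: 1.0e6
  lib_cv: 0.2
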