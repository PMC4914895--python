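# Study-scale synthetic cohort (seven diseases, 22-SNP panel, no true
# modifier effects). Override the seed with --seed on the command line.
seed: 2026
simulate:
  preset: study
  n_snps: 22
  sigma: 0.2
options:
  residual_scale: years
  hwe_threshold: 0.001
  cov_method: polynomial
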