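# Study-scale synthetic run: 150 respondents x 53 ternary items, two
# standardized covariates shifting ability, willingness and guess bias.
generator:
  n_respondents: 150
  n_items: 53
  seed: 7
mcmc:
  n_chains: 4
  n_burnin: 500
  n_samples: 500
  seed: 1
ppc:
  n_replicates: 200
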