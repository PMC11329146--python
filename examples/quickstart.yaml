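# Quick-start synthetic run: huntwatch run --config examples/quickstart.yaml --seed 7 --out out/
simulate:
  n_regions: 6
  provinces_per_region: 5
  theta: 500.0
training_cutoff: 2019
sampler:
  chains: 2
  draws: 1000
  warmup: 1000
selection:
  enabled: false
association:
  policy: flagged
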