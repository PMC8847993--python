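# Small end-to-end preset: 100-gene library, 5 designated synthetic-lethal
# genes, test-scale depth.  Deterministic under the seed.
seed: 7
simulate:
  n_genes: 100
  clones_per_gene: [4, 10]
  n_nontargeting: 30
  depth: 2.0e5
  dispersion: 0.05
  sl_genes: [G0007, G0019, G0042, G0063, G0088]
  fold_depletion: 10.0
  penetrance: 0.8
  seed: 7
hitcall:
  pseudocount: 1.0
  normalization: cpm
  fold_threshold: 5.0
  min_depleted: 2
  min_fivefold: 1
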