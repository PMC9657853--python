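# Nutrient-film-technique profile: 4 cultivars x 4 N treatments x 4 replicates.
profile: nft
seed: 1
window: 13
methods: [FDR, COEF, VIP]
k: 4
h: 3
synthetic:
  noise_sd: 0.01
  n_replicates: 4
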