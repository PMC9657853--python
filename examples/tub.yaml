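# Hydroponic-tub profile: 4 cultivars x 8 N treatments x 4 replicates.
profile: tub
seed: 1
window: 13
use_nds: true
methods: [FDR, COEF, VIP]
k: 6
h: 6
reference_response: NO3_ppm
synthetic:
  noise_sd: 0.01
  n_replicates: 4
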