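# High minor-QTL frequency, 20% introgression at cycle 4, equal index weights.
# Desk-scale profile; drop the `scale` key to run the full-scale programme.
scale: scaled
introgression_pct: 0.20
introgression_cycle: 4
index: {w_disease: 0.5, w_yield: 0.5, k: 0.0}
founder: {minor_freq_mean: 0.85}
h2: [0.5, 0.25]
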