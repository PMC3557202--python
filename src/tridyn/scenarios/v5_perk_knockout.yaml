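# Essential model with the PERK gene silenced (clamped below control).
name: v5_perk_knockout
network: ../models/v5_essential.tsv
stimulus:
  PA: 2
perturbations:
  - kind: knockout_node
    target: PERK
n_runs: 5000
horizon: 40
p: 0.1
seed: 0
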