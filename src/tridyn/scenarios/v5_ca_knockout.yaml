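# Essential model with calcium signaling knocked out.
name: v5_ca_knockout
network: ../models/v5_essential.tsv
stimulus:
  PA: 2
perturbations:
  - kind: knockout_node
    target: Ca
n_runs: 5000
horizon: 40
p: 0.1
seed: 0
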