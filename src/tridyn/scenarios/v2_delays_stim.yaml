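# Palmitate stimulation held above control for the full window.
name: v2_delays_stim
network: ../models/v2_delays.tsv
stimulus:
  PA: 2
perturbations: []
n_runs: 5000
horizon: 40
p: 0.1
seed: 0
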