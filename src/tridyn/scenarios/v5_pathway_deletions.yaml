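# Essential model without the slow PKA arm (the p38/Ras shortcuts are
# already absent from the essential network); calcium signaling alone
# must carry CREB1 activation.
name: v5_pathway_deletions
network: ../models/v5_essential.tsv
stimulus:
  PA: 2
perturbations:
  - kind: delete_edge
    target: [PA, PKA, activate]
n_runs: 5000
horizon: 40
p: 0.1
seed: 0
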