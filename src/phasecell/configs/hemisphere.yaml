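# Validation case: cell landing just off the apex of a 12 um hemisphere,
# membrane tension enabled (compare hemisphere_notension.yaml).
scenario: hemisphere
scenario_args:
  t_end: 300
sample_every: 1.0
snapshot_every: 50
seed: 0
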