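# Bijel-templated material: bicontinuous spinodal structure, cell seeded
# into a snug pore.
scenario: btm
scenario_args:
  t_end: 250
  seed: 3
sample_every: 1.0
snapshot_every: 25
seed: 0
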