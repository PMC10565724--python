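# Tension-free control: epsilon = 0 and f0 = 0 disable the membrane
# tension extension, recovering the predecessor model.
scenario: hemisphere-notension
scenario_args:
  t_end: 300
sample_every: 1.0
snapshot_every: 50
seed: 0
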