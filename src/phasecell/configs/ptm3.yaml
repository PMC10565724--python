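# Simplified particle-templated interconnect: three stacked spherical
# pores; the cell starts low in the middle pocket moving down.
scenario: ptm3
scenario_args:
  t_end: 250
sample_every: 1.0
snapshot_every: 25
seed: 0
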