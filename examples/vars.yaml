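# Per-variable scoring configuration. Unset fields fall back to the shipped
# defaults for height/weight; new variables need a full block.
height:
  cutoff: 0.05
weight:
  tau: 0.5
  var_y: 210.0
  cutoff: 0.05
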