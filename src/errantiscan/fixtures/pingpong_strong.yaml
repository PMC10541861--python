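# Small-RNA library with a strong ping-pong configuration: half of the
# antisense reads carry a sense partner at exactly 10-nt 5'-overlap.
smallrna:
  n_reads: 20000
  sense_fraction: 0.5
  pp_fraction: 0.5
  u1_bias: 0.75
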