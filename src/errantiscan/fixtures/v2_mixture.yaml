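# Equimolar full-length / v2-deletion transcript mixture plus a control
# transcript, for split-read variant quantification.
rnaseq:
  transcripts: {fl: 1.0, v2: 1.0, control: 1.0}
  read_length: 150
  n_reads: 20000
  control_length: 2000
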