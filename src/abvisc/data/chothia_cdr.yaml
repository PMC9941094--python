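# Chothia CDR boundary ranges (inclusive) on Chothia-numbered positions.
light:
  CDR-L1: [24, 34]
  CDR-L2: [50, 56]
  CDR-L3: [89, 97]
heavy:
  CDR-H1: [26, 32]
  CDR-H2: [52, 56]
  CDR-H3: [95, 102]
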