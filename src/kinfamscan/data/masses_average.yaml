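# Average isotopic residue masses (Da), i.e. free amino acid minus one
# water, from the ExPASy Compute pI/Mw mass table; plus the average mass
# of one water molecule added once per chain.
water: 18.0153
residues:
  A: 71.0779
  C: 103.1429
  D: 115.0874
  E: 129.1140
  F: 147.1738
  G: 57.0513
  H: 137.1393
  I: 113.1576
  K: 128.1723
  L: 113.1576
  M: 131.1960
  N: 114.1026
  P: 97.1152
  Q: 128.1292
  R: 156.1857
  S: 87.0773
  T: 101.1039
  V: 99.1310
  W: 186.2099
  Y: 163.1732
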