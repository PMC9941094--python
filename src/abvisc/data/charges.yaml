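# Minimal per-atom partial-charge table for ESP generation.
# Formal charges are localized on the ionizable side-chain groups; the
# backbone carries a small, internally neutral dipole (N/CA and C/O pairs
# cancel), so every residue sums exactly to its formal charge.
backbone:
  N: -0.47
  CA: 0.47
  C: 0.51
  O: -0.51
sidechain:
  ASP: {OD1: -0.5, OD2: -0.5}
  GLU: {OE1: -0.5, OE2: -0.5}
  LYS: {NZ: 1.0}
  ARG: {NH1: 0.5, NH2: 0.5}
# applied only when His is configured protonated (+1)
his_plus: {ND1: 0.5, NE2: 0.5}
formal_charges:
  ASP: -1.0
  GLU: -1.0
  LYS: 1.0
  ARG: 1.0
# applied only when charged termini are enabled
termini:
  n_term: {N: 1.0}
  c_term: {O: -0.5, OXT: -0.5}
# van der Waals radii (Angstrom) per element; united-atom variants are used
# when the structure carries no hydrogens
radii:
  H: 1.20
  C: 1.70
  N: 1.55
  O: 1.52
  S: 1.80
  P: 1.80
  default: 1.70
radii_united:
  C: 1.90
  N: 1.70
  O: 1.60
  S: 2.00
  P: 2.00
  default: 1.90
masses:
  H: 1.008
  C: 12.011
  N: 14.007
  O: 15.999
  S: 32.06
  P: 30.974
  default: 12.011
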