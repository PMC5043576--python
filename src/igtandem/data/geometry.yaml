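# Geometric constants used across the package. Editable: pass an override
# dict to the functions that consume these, or edit in place.

# van der Waals radii (Angstrom) for SASA; element-keyed.
vdw_radii:
  C: 1.70
  N: 1.55
  O: 1.52
  S: 1.80
  P: 1.80
  H: 1.20

# Solvent probe radius (Angstrom).
probe_radius: 1.4

# Idealized backbone internal coordinates (Engh/Huber-style averages).
backbone:
  bond_n_ca: 1.458
  bond_ca_c: 1.525
  bond_c_n: 1.329
  bond_c_o: 1.231
  bond_ca_cb: 1.530
  angle_n_ca_c: 111.2
  angle_ca_c_n: 116.2
  angle_c_n_ca: 121.7
  angle_ca_c_o: 120.8
  angle_n_ca_cb: 110.5
  # improper torsion N-C-CA-CB fixing L-chirality
  improper_n_c_ca_cb: 122.6

# Peptide-bond continuity: C(i-1)-N(i) distances above this are chain breaks.
chain_break_cn: 2.0
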