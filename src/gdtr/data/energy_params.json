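{
  "_comment": "United heavy-atom parameters for the pairwise interface energy model. lj: per-element Lennard-Jones minimum-energy distance rmin (A) and well depth eps (kcal/mol). charges: formal side-chain charges (e) spread over the charged-group atoms. Values are a generic united-atom set; the energy model is a transparent scoring function, not a calibrated force field.",
  "lj": {
    "C": {"rmin": 4.00, "eps": 0.15},
    "N": {"rmin": 3.60, "eps": 0.16},
    "O": {"rmin": 3.40, "eps": 0.20},
    "S": {"rmin": 4.00, "eps": 0.20},
    "X": {"rmin": 3.80, "eps": 0.15}
  },
  "charges": {
    "ASP": {"OD1": -0.5, "OD2": -0.5},
    "GLU": {"OE1": -0.5, "OE2": -0.5},
    "LYS": {"NZ": 1.0},
    "ARG": {"NE": 0.3333333333, "NH1": 0.3333333333, "NH2": 0.3333333333},
    "HIS": {"ND1": 0.25, "NE2": 0.25}
  },
  "hbond_well": -1.0,
  "hbond_min": 2.4,
  "hbond_max": 3.5,
  "desolvation_per_contact": -0.025,
  "desolvation_cutoff": 5.0,
  "coulomb_constant": 332.0636,
  "dielectric_slope": 4.0,
  "pair_cutoff": 12.0,
  "cap_distance": 1.0
}
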