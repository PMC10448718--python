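{
  "comment": "Published empirical docking-score terms: weights and van der Waals radii. Distances are surface distances d = r - R_i - R_j; cutoff 8 A.",
  "weights": {
    "gauss1": -0.035579,
    "gauss2": -0.005156,
    "repulsion": 0.840245,
    "hydrophobic": -0.035069,
    "hbond": -0.587439
  },
  "gauss1": {"offset": 0.0, "width": 0.5},
  "gauss2": {"offset": 3.0, "width": 2.0},
  "hydrophobic": {"good": 0.5, "bad": 1.5},
  "hbond": {"good": -0.7, "bad": 0.0},
  "cutoff": 8.0,
  "xs_radii": {
    "C": 1.9, "N": 1.8, "O": 1.7, "S": 2.0, "P": 2.1,
    "F": 1.5, "CL": 1.8, "BR": 2.0, "I": 2.2
  },
  "chpi": {
    "h_dependent": {"E": 0.29, "R0": 3.58, "C": 0.85},
    "h_independent": {"E": 0.26, "R0": 4.49, "C": 0.75},
    "pair_scale": 0.5,
    "default_weight": 0.3
  }
}
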