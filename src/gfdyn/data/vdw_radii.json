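{
  "comment": "Bondi-style van der Waals radii in Angstroms; X is the pseudo-glycan occluder sphere used by the synthetic generator",
  "radii": {
    "H": 1.2,
    "C": 1.7,
    "N": 1.55,
    "O": 1.52,
    "S": 1.8,
    "P": 1.8,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "NA": 2.27,
    "K": 2.75,
    "MG": 1.73,
    "CA": 2.31,
    "ZN": 1.39,
    "FE": 1.94,
    "X": 3.0
  }
}
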