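{
  "_comment": "Synthetic residue-level force field for RNA/peptide coacervate simulation. One bead per nucleotide (A, U, C) or amino acid (R = arginine, P = proline). Charges: nucleotide -1 e, arginine +1 e, proline 0. The Wang-Frenkel sticker table is a synthetic stand-in constructed for this package (not a published parameter set); it preserves the qualitative ordering that adenine-adenine pi-stacking is the strongest base-base contact and that arginine-base cross terms are strong. Energies kJ/mol, lengths Angstrom, masses amu.",
  "beads": {
    "A": {"mass": 329.2, "charge": -1.0, "class": "nucleic"},
    "U": {"mass": 306.2, "charge": -1.0, "class": "nucleic"},
    "C": {"mass": 305.2, "charge": -1.0, "class": "nucleic"},
    "R": {"mass": 156.19, "charge": 1.0, "class": "amino"},
    "P": {"mass": 97.12, "charge": 0.0, "class": "amino"}
  },
  "harmonic": {"K": 9.6, "rref": {"nucleic": 5.0, "amino": 3.81}},
  "electrostatics": {"epsilon_r": 80.0, "cutoff": 35.0},
  "wang_frenkel": {
    "mu": 2, "nu": 1, "rc_over_sigma": 3.0,
    "sigma": {"A": 6.0, "U": 6.0, "C": 6.0, "R": 5.0, "P": 5.0},
    "epsilon_pairs": {
      "A-A": 3.50, "U-U": 1.40, "C-C": 1.60,
      "A-U": 2.20, "A-C": 2.35, "U-C": 1.50,
      "R-A": 4.00, "R-U": 2.80, "R-C": 2.90,
      "R-R": 0.50, "P-A": 0.80, "P-U": 0.60, "P-C": 0.65,
      "P-R": 0.45, "P-P": 0.40
    }
  }
}
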