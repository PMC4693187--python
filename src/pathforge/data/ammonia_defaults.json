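{
  "_comment": "Synthetic, user-supplied default thermodynamic data for the ammonia assimilation fixture. dg0 in kJ/mol, concentrations in mol/L. These are placeholder values of literature-like magnitude chosen for reproducible offline tests; substitute curated values for quantitative work.",
  "dg0": {
    "GDH": -25.0,
    "GS": -15.0,
    "GOGAT": -20.0
  },
  "concentrations": {
    "NH3": 1e-3,
    "AKG": 1e-2,
    "ATP": 1e-3,
    "ADP": 1e-3,
    "Pi": 1e-3,
    "NADPH": 1e-3,
    "NADP": 1e-3,
    "GLU": 1e-3,
    "GLN": 1e-3
  }
}
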