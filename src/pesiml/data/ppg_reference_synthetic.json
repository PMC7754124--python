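{
  "description": "SYNTHETIC calibration reference: glycerol-initiated polypropylene glycol (triol PPG) [M+Na]+ oligomer series with plausible relative intensities. The vendor's monitored ion list is unpublished; this file is a stand-in for daily mass-accuracy and intensity-ratio checks.",
  "mass_tol_da": 0.5,
  "ratio_tol_fraction": 0.30,
  "peaks": [
    {"mz": 289.20, "relative_intensity": 0.35},
    {"mz": 347.24, "relative_intensity": 0.60},
    {"mz": 405.28, "relative_intensity": 0.85},
    {"mz": 463.33, "relative_intensity": 1.0},
    {"mz": 521.37, "relative_intensity": 0.80},
    {"mz": 579.41, "relative_intensity": 0.55},
    {"mz": 637.45, "relative_intensity": 0.35},
    {"mz": 695.49, "relative_intensity": 0.20},
    {"mz": 753.53, "relative_intensity": 0.10}
  ]
}
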