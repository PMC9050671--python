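{
  "_comment": "Alternative calibration using the rounded per-nucleotide conductances (87/67/60/36/18 pS) sometimes quoted for this sensor; the packaged default uses the histogram-peak values instead.",
  "reference_base": "G",
  "classes": {
    "G": {"nominal_pS": 87.0},
    "A": {"nominal_pS": 67.0},
    "C": {"nominal_pS": 60.0},
    "T": {"nominal_pS": 36.0},
    "F": {"nominal_pS": 18.0}
  }
}
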