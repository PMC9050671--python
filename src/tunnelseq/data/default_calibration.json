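{
  "reference_base": "G",
  "classes": {
    "G": {"nominal_pS": 86.7, "noise_sd_pS": 8.67},
    "A": {"nominal_pS": 66.8, "noise_sd_pS": 6.68},
    "C": {"nominal_pS": 59.5, "noise_sd_pS": 5.95},
    "T": {"nominal_pS": 39.1, "noise_sd_pS": 3.91},
    "F": {"nominal_pS": 17.9, "noise_sd_pS": 1.79}
  }
}
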