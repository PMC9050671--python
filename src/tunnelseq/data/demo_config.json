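{
  "seed": 7,
  "label": "demo",
  "simulation": {
    "template_sequence": "AGACATGCCCAGACATGCCC",
    "ftd_substitution_prob": 0.10,
    "n_events": 500,
    "read_truncation": [5, 20]
  }
}
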