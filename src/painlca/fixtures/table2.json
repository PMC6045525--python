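{
  "name": "table2",
  "description": "Pooled three-class model of four binary pain items. Entries published as '< 0.01' are encoded as 0.0; this encoding reproduces the published model-implied marginal prevalences (27.9% neck, 20.7% shoulder).",
  "item_names": ["neck", "shoulder", "upper_back", "low_back"],
  "class_names": ["minor", "moderate", "major"],
  "group_names": ["all"],
  "group_fractions": [1.0],
  "default_n": 1611,
  "gamma": [[0.327, 0.602, 0.071]],
  "rho": [
    [
      [0.0, 0.04, 0.0, 0.13],
      [0.36, 0.24, 0.24, 0.38],
      [0.88, 0.70, 0.65, 1.00]
    ]
  ],
  "anomalies": []
}
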