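{
  "name": "table4_age",
  "description": "Age-specific three-class model (<=13 vs >=14 years). Values are encoded exactly as published.",
  "item_names": ["neck", "shoulder", "upper_back", "low_back"],
  "class_names": ["minor", "moderate", "major"],
  "group_names": ["le13", "ge14"],
  "group_fractions": [0.527, 0.473],
  "default_n": 1611,
  "gamma": [
    [0.291, 0.639, 0.070],
    [0.614, 0.333, 0.053]
  ],
  "rho": [
    [
      [0.07, 0.0, 0.0, 0.02],
      [0.30, 0.27, 0.44, 0.21],
      [0.97, 0.69, 1.00, 0.57]
    ],
    [
      [0.0, 0.09, 0.24, 0.08],
      [0.71, 0.29, 0.42, 0.30],
      [0.70, 0.71, 1.00, 1.00]
    ]
  ],
  "anomalies": [
    "The published low-back and upper-back rows are mutually inconsistent with the pooled and gender-age tables (upper-back major-class probability printed as 1.00 in both age bands while low-back is 0.57/1.00), suggesting a possible row-label swap in the source table. Values are stored as published, not corrected."
  ]
}
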