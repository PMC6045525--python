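{
  "name": "table5_gender_age",
  "description": "Gender-age (four-stratum) three-class model with the published stratum fractions (29.8, 23.1, 22.9, 24.2)%.",
  "item_names": ["neck", "shoulder", "upper_back", "low_back"],
  "class_names": ["minor", "moderate", "major"],
  "group_names": ["girls_le13", "girls_ge14", "boys_le13", "boys_ge14"],
  "group_fractions": [0.298, 0.231, 0.229, 0.242],
  "default_n": 1611,
  "gamma": [
    [0.388, 0.312, 0.300],
    [0.355, 0.597, 0.048],
    [0.286, 0.367, 0.347],
    [0.778, 0.054, 0.168]
  ],
  "rho": [
    [
      [0.0, 0.0, 0.08, 0.22],
      [0.39, 0.28, 0.18, 0.0],
      [0.55, 0.48, 0.31, 1.00]
    ],
    [
      [0.10, 0.07, 0.0, 0.0],
      [0.32, 0.25, 0.23, 0.43],
      [1.00, 0.75, 0.87, 1.00]
    ],
    [
      [0.14, 0.0, 0.08, 0.63],
      [0.10, 0.19, 0.06, 0.0],
      [0.67, 0.49, 0.53, 0.65]
    ],
    [
      [0.13, 0.03, 0.09, 0.22],
      [0.49, 1.00, 0.0, 0.0],
      [0.66, 0.39, 0.63, 0.65]
    ]
  ],
  "anomalies": []
}
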