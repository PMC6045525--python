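{
  "name": "table3_gender",
  "description": "Gender-specific three-class model. Girl fraction = 0.298 + 0.231 of the published stratum split. The boy membership row is published as (34.5, 61.6, 4.0)% summing to 100.1%; the loader renormalises.",
  "item_names": ["neck", "shoulder", "upper_back", "low_back"],
  "class_names": ["minor", "moderate", "major"],
  "group_names": ["girl", "boy"],
  "group_fractions": [0.529, 0.471],
  "default_n": 1611,
  "gamma": [
    [0.307, 0.579, 0.114],
    [0.345, 0.616, 0.040]
  ],
  "rho": [
    [
      [0.0, 0.02, 0.0, 0.18],
      [0.35, 0.27, 0.25, 0.38],
      [0.84, 0.61, 0.50, 1.00]
    ],
    [
      [0.0, 0.04, 0.0, 0.08],
      [0.35, 0.21, 0.23, 0.36],
      [0.94, 0.79, 0.95, 1.00]
    ]
  ],
  "anomalies": []
}
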