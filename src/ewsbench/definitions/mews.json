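{
  "name": "MEWS",
  "theoretical_range": [0, 14],
  "components": [
    {
      "variable": "sbp",
      "resolution": 1,
      "bands": [
        [null, 70, 3],
        [71, 80, 2],
        [81, 100, 1],
        [101, 199, 0],
        [200, null, 2]
      ]
    },
    {
      "variable": "hr",
      "resolution": 1,
      "bands": [
        [null, 40, 2],
        [41, 50, 1],
        [51, 100, 0],
        [101, 110, 1],
        [111, 129, 2],
        [130, null, 3]
      ]
    },
    {
      "variable": "rr",
      "resolution": 1,
      "bands": [
        [null, 8, 2],
        [9, 14, 0],
        [15, 20, 1],
        [21, 29, 2],
        [30, null, 3]
      ]
    },
    {
      "variable": "temp",
      "resolution": 0.1,
      "bands": [
        [null, 34.9, 2],
        [35.0, 38.4, 0],
        [38.5, null, 2]
      ]
    },
    {
      "variable": "avpu",
      "categorical_points": {"A": 0, "V": 1, "P": 2, "U": 3}
    }
  ],
  "special_rules": {}
}
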