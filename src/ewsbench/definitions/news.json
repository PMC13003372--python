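{
  "name": "NEWS",
  "theoretical_range": [0, 20],
  "components": [
    {
      "variable": "rr",
      "resolution": 1,
      "bands": [
        [null, 8, 3],
        [9, 11, 1],
        [12, 20, 0],
        [21, 24, 2],
        [25, null, 3]
      ]
    },
    {
      "variable": "spo2",
      "resolution": 1,
      "bands": [
        [null, 91, 3],
        [92, 93, 2],
        [94, 95, 1],
        [96, null, 0]
      ]
    },
    {
      "variable": "on_oxygen",
      "categorical_points": {"true": 2, "false": 0}
    },
    {
      "variable": "temp",
      "resolution": 0.1,
      "bands": [
        [null, 35.0, 3],
        [35.1, 36.0, 1],
        [36.1, 38.0, 0],
        [38.1, 39.0, 1],
        [39.1, null, 2]
      ]
    },
    {
      "variable": "sbp",
      "resolution": 1,
      "bands": [
        [null, 90, 3],
        [91, 100, 2],
        [101, 110, 1],
        [111, 219, 0],
        [220, null, 3]
      ]
    },
    {
      "variable": "hr",
      "resolution": 1,
      "bands": [
        [null, 40, 3],
        [41, 50, 1],
        [51, 90, 0],
        [91, 110, 1],
        [111, 130, 2],
        [131, null, 3]
      ]
    },
    {
      "variable": "avpu",
      "categorical_points": {"A": 0, "V": 3, "P": 3, "U": 3}
    }
  ],
  "special_rules": {}
}
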