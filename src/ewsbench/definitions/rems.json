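{
  "name": "REMS",
  "theoretical_range": [0, 26],
  "components": [
    {
      "variable": "age",
      "resolution": 1,
      "bands": [
        [null, 44, 0],
        [45, 54, 2],
        [55, 64, 3],
        [65, 74, 5],
        [75, null, 6]
      ]
    },
    {
      "variable": "map",
      "resolution": 1,
      "bands": [
        [null, 49, 4],
        [50, 69, 2],
        [70, 109, 0],
        [110, 129, 2],
        [130, 159, 3],
        [160, null, 4]
      ]
    },
    {
      "variable": "hr",
      "resolution": 1,
      "bands": [
        [null, 39, 4],
        [40, 54, 3],
        [55, 69, 2],
        [70, 109, 0],
        [110, 139, 2],
        [140, 179, 3],
        [180, null, 4]
      ]
    },
    {
      "variable": "rr",
      "resolution": 1,
      "bands": [
        [null, 5, 4],
        [6, 9, 2],
        [10, 11, 1],
        [12, 24, 0],
        [25, 34, 1],
        [35, 49, 3],
        [50, null, 4]
      ]
    },
    {
      "variable": "spo2",
      "resolution": 1,
      "bands": [
        [null, 74, 4],
        [75, 85, 3],
        [86, 89, 1],
        [90, null, 0]
      ]
    },
    {
      "variable": "gcs",
      "resolution": 1,
      "bands": [
        [null, 4, 4],
        [5, 7, 3],
        [8, 10, 2],
        [11, 13, 1],
        [14, null, 0]
      ]
    }
  ],
  "special_rules": {}
}
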