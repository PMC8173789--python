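{
  "name": "our_center",
  "statistic": "mean",
  "description": "Four-level thresholds on all five indexes; Level 4 only at the exact perfect value.",
  "indexes": {
    "dsc": {"direction": "higher", "cutpoints": [0.7, 0.8], "perfect": 1.0},
    "cmd": {"direction": "lower", "cutpoints": [0.5, 1.0], "perfect": 0.0},
    "dv":  {"direction": "lower", "cutpoints": [10.0, 20.0], "perfect": 0.0},
    "mhd": {"direction": "lower", "cutpoints": [1.0, 2.2], "perfect": 0.0},
    "ahd": {"direction": "lower", "cutpoints": [0.2, 0.4], "perfect": 0.0}
  }
}
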