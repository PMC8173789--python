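{
  "name": "ciardo",
  "statistic": "median",
  "description": "Three-level scheme on DSC, centroid distance and average Hausdorff distance.",
  "indexes": {
    "dsc": {"direction": "higher", "cutpoints": [0.6, 0.8]},
    "cmd": {"direction": "lower", "cutpoints": [0.2, 0.5]},
    "ahd": {"direction": "lower", "cutpoints": [0.15, 0.4]}
  }
}
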