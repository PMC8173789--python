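{
  "name": "velker",
  "statistic": "mean",
  "description": "Three-level DSC-only scheme: poor [0,0.6), medium [0.6,0.8), good [0.8,1].",
  "indexes": {
    "dsc": {"direction": "higher", "cutpoints": [0.6, 0.8]}
  }
}
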