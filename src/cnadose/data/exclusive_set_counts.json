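{
  "n_high": 1757,
  "n_low": 1104,
  "n_common": 895,
  "strata": {
    "ge6": 79,
    "4to5": 118,
    "1to3": 370,
    "0": 295
  }
}
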