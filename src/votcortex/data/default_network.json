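{
  "unit_names": ["burst_detector", "voicing_detector", "inhibitory", "gap", "coinc"],
  "units": {
    "burst_detector":  {"resting": 0.0, "minimum": -5.0, "maximum": 5.0, "decay": 2.0, "threshold": 0.5},
    "voicing_detector": {"resting": 0.0, "minimum": -5.0, "maximum": 5.0, "decay": 2.0, "threshold": 0.5},
    "inhibitory":      {"resting": 0.0, "minimum": -5.0, "maximum": 5.0, "decay": 2.0, "threshold": 0.5},
    "gap":             {"resting": 0.0, "minimum": -5.0, "maximum": 5.0, "decay": 0.2, "threshold": 0.95},
    "coinc":           {"resting": 0.0, "minimum": -5.0, "maximum": 5.0, "decay": 0.3, "threshold": 1.2}
  },
  "weights": [
    ["burst_detector", "inhibitory", 1.0],
    ["burst_detector", "gap", 1.0],
    ["burst_detector", "coinc", 1.0],
    ["voicing_detector", "gap", 1.9],
    ["voicing_detector", "coinc", 1.9],
    ["inhibitory", "gap", -2.2]
  ],
  "n_cycles": 100,
  "ms_per_cycle": 10,
  "inputs": {
    "burst_magnitude": 1.0,
    "voicing_magnitude": 1.0,
    "burst_onset_cycle": 2,
    "voicing_lag_cycles": 1
  }
}
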