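{
  "truth_D": 400.0,
  "spec": {
    "spot_center": 10.0,
    "spot_width": 1.0,
    "n_locations": 8,
    "location_step": 0.6,
    "line_period": 0.0007,
    "duration": 0.03,
    "noise_sd": 0.03,
    "replicates": 10,
    "domain_length": 20.0,
    "dx": 0.05,
    "rng_seed": 42
  }
}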