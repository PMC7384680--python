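{
  "out_dir": "runs/demo",
  "scenarios": ["A", "B", "C", "D", "E", "F", "G", "H"],
  "n_members": 500,
  "seed": 0,
  "synth_noise_sd": 0.1,
  "synth_scenario": "C",
  "enrich_params": ["d_A", "k_C", "chi"]
}
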