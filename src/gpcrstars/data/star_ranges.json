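[
  {"name": "errat", "direction": "higher-better", "thresholds": [100.0, 99.0, 98.0], "weight": 1.0},
  {"name": "verify3d", "direction": "higher-better", "thresholds": [73.0, 67.0, 61.0], "weight": 1.0},
  {"name": "prove", "direction": "lower-better", "thresholds": [2.8, 3.2, 3.6], "weight": 1.0},
  {"name": "rama_core", "direction": "higher-better", "thresholds": [94.4, 93.7, 93.0], "weight": 0.5},
  {"name": "rama_disallowed", "direction": "lower-better", "thresholds": [0.0, 0.4, 0.8], "weight": 0.5},
  {"name": "labelled_residues", "direction": "lower-better", "thresholds": [3.0, 5.0, 7.0], "weight": 1.0},
  {"name": "rwplus", "direction": "lower-better", "thresholds": [-79000.0, -78250.0, -77500.0], "weight": 1.0},
  {"name": "molprobity", "direction": "lower-better", "thresholds": [1.0, 1.2, 1.4], "weight": 1.0},
  {"name": "rosetta", "direction": "lower-better", "thresholds": [-750.0, -675.0, -600.0], "weight": 1.0},
  {"name": "dfire", "direction": "lower-better", "thresholds": [-649.0, -641.0, -633.0], "weight": 1.0},
  {"name": "goap", "direction": "lower-better", "thresholds": [-37200.0, -36000.0, -34800.0], "weight": 1.0},
  {"name": "opus_psp", "direction": "lower-better", "thresholds": [-5770.0, -5650.0, -5530.0], "weight": 1.0},
  {"name": "predicted_global_quality", "direction": "higher-better", "thresholds": [0.26, 0.24, 0.22], "weight": 1.0}
]
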