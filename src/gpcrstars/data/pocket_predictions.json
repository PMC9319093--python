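{
  "description": "Synthetic per-model pocket-residue predictions emulating ligand-site-prediction output for eight GPR18 models. Constructed so that the 15 consensus residues reported for the receptor's putative orthosteric pocket (2.60, 2.63, 2.64, 3.32, 45.50, 45.51, 45.52, 5.42, 6.51, 6.55, 6.58, 7.32, 7.35, 7.36, 7.39) are each predicted by at least 6 of the 8 models, while deep-EL2 and other sporadic residues stay below that count.",
  "consensus_min_models": 6,
  "predictions": [
    {
      "model_id": "CIT_1",
      "pocket_size": 96,
      "residues": ["2.60", "2.63", "2.64", "3.32", "45.50", "45.51", "45.52", "5.42", "6.51", "6.55", "6.58", "7.32", "7.35", "7.36", "7.39", "res:A:175", "2.57"]
    },
    {
      "model_id": "TTA_5",
      "pocket_size": 130,
      "residues": ["2.60", "2.63", "2.64", "3.32", "45.50", "45.51", "45.52", "5.42", "6.51", "6.55", "6.58", "7.32", "7.35", "7.36", "7.39", "res:A:175", "res:A:176", "7.31"]
    },
    {
      "model_id": "IT_1",
      "pocket_size": 118,
      "residues": ["2.60", "2.63", "2.64", "3.32", "45.50", "45.51", "45.52", "5.42", "6.51", "6.55", "6.58", "7.32", "7.35", "7.36", "7.39", "res:A:175", "2.57"]
    },
    {
      "model_id": "PY3_10",
      "pocket_size": 104,
      "residues": ["2.60", "2.63", "2.64", "3.32", "45.50", "45.51", "45.52", "5.42", "6.51", "6.55", "6.58", "7.32", "7.35", "7.36", "7.39", "res:A:175"]
    },
    {
      "model_id": "TR_1",
      "pocket_size": 110,
      "residues": ["2.60", "2.63", "2.64", "3.32", "45.50", "45.51", "45.52", "5.42", "6.51", "6.55", "6.58", "7.32", "7.35", "7.36", "7.39", "res:A:175", "res:A:176", "7.31"]
    },
    {
      "model_id": "CF-DM",
      "pocket_size": 92,
      "residues": ["2.60", "2.63", "2.64", "3.32", "45.50", "45.51", "45.52", "5.42", "6.51", "6.55", "6.58", "7.32", "7.35", "7.36", "7.39", "res:A:176", "7.31", "1.39"]
    },
    {
      "model_id": "PF-DM",
      "pocket_size": 98,
      "residues": ["2.60", "2.63", "2.64", "3.32", "45.50", "45.51", "45.52", "5.42", "6.51", "6.55", "7.32", "7.36", "7.39", "res:A:176", "7.31"]
    },
    {
      "model_id": "AF-DM",
      "pocket_size": 74,
      "residues": ["2.60", "2.63", "2.64", "3.32", "45.50", "45.52", "6.51", "6.55", "7.32", "7.35", "7.31", "4.60", "4.64"]
    }
  ]
}
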