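[
  {"pdb_id": "8EF5", "chain": "R", "label": "8EF5_R"},
  {"pdb_id": "8EF5", "chain": "M", "label": "8EF5_M"},
  {"pdb_id": "4DKL", "chain": "A", "label": "4DKL_A"},
  {"pdb_id": "8QOT", "chain": "A", "label": "8QOT_A"},
  {"pdb_id": "7UL4", "chain": "A", "label": "7UL4_A"},
  {"pdb_id": "8E0G", "chain": "A", "label": "8E0G_A"},
  {"pdb_id": "5C1M", "chain": "A", "label": "5C1M_A"},
  {"pdb_id": "6DDE", "chain": "R", "label": "6DDE_R"},
  {"pdb_id": "8F7R", "chain": "M", "label": "8F7R_M"},
  {"pdb_id": "8F7Q", "chain": "M", "label": "8F7Q_M"},
  {"pdb_id": "8EFB", "chain": "R", "label": "8EFB_R"},
  {"pdb_id": "7SBF", "chain": "R", "label": "7SBF_R"}
]
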