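{
  "name": "heart_field",
  "inputs": ["ex_WNT", "ex_BMP2"],
  "fixed_inputs": {"ex_BMP2": 1},
  "condition_axes": {"WNT": "ex_WNT"},
  "conditions": [
    {"name": "WNT=0", "levels": {"WNT": 0}, "expected_lineage": "FHF"},
    {"name": "WNT=1", "levels": {"WNT": 1}, "expected_lineage": "SHF"}
  ],
  "signatures": [
    {"label": "FHF", "require": {"GATA4_6": 1, "TBX5": 1}},
    {"label": "SHF", "require": {"GATA4_6": 1, "ISL1": 1, "TBX1": 1}},
    {"label": "null", "require": {"GATA4_6": 0}}
  ],
  "steady_state_table": [
    {
      "label": "FHF",
      "condition": {"WNT": 0},
      "state": {
        "EX_WNT": 0, "EX_BMP2": 1, "BMP2": 1, "WNT": 0, "FOXC1_2": 0,
        "ISL1": 0, "MESP1": 0, "NKX2_5": 1, "TBX1": 0, "TBX5": 1, "GATA4_6": 1
      }
    },
    {
      "label": "null",
      "condition": {"WNT": 0},
      "state": {
        "EX_WNT": 0, "EX_BMP2": 1, "BMP2": 1, "WNT": 0, "FOXC1_2": 0,
        "ISL1": 0, "MESP1": 0, "NKX2_5": 0, "TBX1": 0, "TBX5": 0, "GATA4_6": 0
      }
    },
    {
      "label": "SHF",
      "condition": {"WNT": 1},
      "state": {
        "EX_WNT": 1, "EX_BMP2": 1, "BMP2": 0, "WNT": 1, "FOXC1_2": 1,
        "ISL1": 1, "MESP1": 0, "NKX2_5": 1, "TBX1": 1, "TBX5": 0, "GATA4_6": 1
      }
    }
  ],
  "provenance": {
    "rules": "constrained reconstruction of the adapted single-exogen heart-field network; exact published update functions live in supplementary material not reproduced here, so this rule set is validated against the steady-state table and the population absorption split and is swappable",
    "printed": [],
    "reconstructed": ["WNT", "BMP2", "FOXC1_2", "MESP1", "ISL1", "GATA4_6", "NKX2_5", "TBX1", "TBX5"]
  }
}
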