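{
  "name": "unified",
  "inputs": ["ex_WNT", "ex_BMP2", "ex_FGF8", "NOTCH", "RA"],
  "fixed_inputs": {"ex_BMP2": 1, "ex_FGF8": 1, "NOTCH": 1},
  "condition_axes": {"WNT": "ex_WNT", "RA": "RA"},
  "conditions": [
    {"name": "WNT=0,RA=0", "levels": {"WNT": 0, "RA": 0}, "expected_lineage": "FHF_vCM"},
    {"name": "WNT=1,RA=0", "levels": {"WNT": 1, "RA": 0}, "expected_lineage": "SHF_vCM"},
    {"name": "WNT=0,RA=1", "levels": {"WNT": 0, "RA": 1}, "expected_lineage": "FHF_aCM"},
    {"name": "WNT=1,RA=1", "levels": {"WNT": 1, "RA": 1}, "expected_lineage": "SHF_aCM"}
  ],
  "signatures": [
    {"label": "FHF_aCM", "require": {"GATA4_6": 1, "TBX5": 1, "MYL7": 1, "MYL2": 0}},
    {"label": "FHF_vCM", "require": {"GATA4_6": 1, "TBX5": 1, "MYL2": 1, "MYL7": 0}},
    {"label": "SHF_aCM", "require": {"GATA4_6": 1, "ISL1": 1, "TBX1": 1, "MYL7": 1, "MYL2": 0}},
    {"label": "SHF_vCM", "require": {"GATA4_6": 1, "ISL1": 1, "TBX1": 1, "MYL2": 1, "MYL7": 0}},
    {"label": "null", "require": {"GATA4_6": 0}}
  ],
  "steady_state_table": [
    {
      "label": "FHF_aCM",
      "condition": {"WNT": 0, "RA": 1},
      "state": {
        "BMP2": 1, "WNT": 0, "TBX5": 1, "ISL1": 0, "TBX1": 0, "GATA4_6": 1,
        "RA": 1, "NR2F2": 1, "MYL7": 1, "IRX4": 0, "MYL2": 0
      }
    },
    {
      "label": "FHF_vCM",
      "condition": {"WNT": 0, "RA": 0},
      "state": {
        "BMP2": 1, "WNT": 0, "TBX5": 1, "ISL1": 0, "TBX1": 0, "GATA4_6": 1,
        "RA": 0, "NR2F2": 0, "MYL7": 0, "IRX4": 1, "MYL2": 1
      }
    },
    {
      "label": "SHF_aCM",
      "condition": {"WNT": 1, "RA": 1},
      "state": {
        "BMP2": 0, "WNT": 1, "TBX5": 0, "ISL1": 1, "TBX1": 1, "GATA4_6": 1,
        "RA": 1, "NR2F2": 1, "MYL7": 1, "IRX4": 0, "MYL2": 0
      }
    },
    {
      "label": "SHF_vCM",
      "condition": {"WNT": 1, "RA": 0},
      "state": {
        "BMP2": 0, "WNT": 1, "TBX5": 0, "ISL1": 1, "TBX1": 1, "GATA4_6": 1,
        "RA": 0, "NR2F2": 0, "MYL7": 0, "IRX4": 1, "MYL2": 1
      }
    },
    {
      "label": "null",
      "condition": {"WNT": 0, "RA": 0},
      "state": {
        "BMP2": 1, "WNT": 0, "TBX5": 0, "ISL1": 0, "TBX1": 0, "GATA4_6": 0,
        "NR2F2": 0, "MYL7": 0, "IRX4": 0, "MYL2": 0
      }
    },
    {
      "label": "null",
      "condition": {"WNT": 0, "RA": 1},
      "state": {
        "BMP2": 1, "WNT": 0, "TBX5": 0, "ISL1": 0, "TBX1": 0, "GATA4_6": 0,
        "NR2F2": 0, "MYL7": 0, "IRX4": 0, "MYL2": 0
      }
    }
  ],
  "provenance": {
    "rules": "heart-field half is the constrained reconstruction; subtype half follows the published algebra with coupling through GATA4/6 (gating NR2F2) and NKX2-5 (gating IRX4); FGF8/ex_FGF8 complete the declared 21-variable count and are inert",
    "printed": ["NR2F2", "HEY2", "MYL7", "HAND2", "MYL2"],
    "reconstructed": ["WNT", "BMP2", "FGF8", "FOXC1_2", "MESP1", "ISL1", "GATA4_6", "NKX2_5", "TBX1", "TBX5", "IRX4"],
    "heart_field_rows": "the steady-state table uses the heart-field marker convention of the two-field table (TBX5 marks FHF; ISL1/TBX1 mark SHF)"
  }
}
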