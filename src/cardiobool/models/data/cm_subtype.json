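{
  "name": "cm_subtype",
  "inputs": ["NOTCH", "RA", "GATA4_6"],
  "fixed_inputs": {"NOTCH": 1, "GATA4_6": 1},
  "condition_axes": {"RA": "RA"},
  "conditions": [
    {"name": "RA=1", "levels": {"RA": 1}, "expected_lineage": "aCM"},
    {"name": "RA=0", "levels": {"RA": 0}, "expected_lineage": "vCM"}
  ],
  "signatures": [
    {"label": "aCM", "require": {"MYL7": 1, "MYL2": 0}},
    {"label": "vCM", "require": {"MYL2": 1, "MYL7": 0}}
  ],
  "steady_state_table": [
    {
      "label": "aCM",
      "condition": {"RA": 1},
      "state": {
        "NOTCH": 1, "RA": 1, "GATA4_6": 1, "NR2F2": 1, "HAND2": 1,
        "IRX4": 0, "HEY2": 0, "MYL2": 0, "MYL7": 1
      }
    },
    {
      "label": "vCM",
      "condition": {"RA": 0},
      "state": {
        "NOTCH": 1, "RA": 0, "GATA4_6": 1, "NR2F2": 0, "HAND2": 1,
        "IRX4": 1, "HEY2": 1, "MYL2": 1, "MYL7": 0
      }
    }
  ],
  "provenance": {
    "rules": "reconstructed from the published continuous update algebra; RA repression of ventricular targets routed through NR2F2",
    "printed": ["NR2F2", "HEY2", "MYL7", "HAND2", "IRX4", "MYL2"],
    "reconstructed": []
  }
}
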