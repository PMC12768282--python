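{
  "description": "Knockout/overexpression battery with literature-expected presence of each condition's cell type (1 = the cell type is observed experimentally under that perturbation, 0 = it is lost).",
  "condition_order": ["WNT=0,RA=1", "WNT=0,RA=0", "WNT=1,RA=1", "WNT=1,RA=0"],
  "experiments": [
    {
      "id": "WT",
      "label": "wild type",
      "perturbations": [],
      "expected": {"WNT=0,RA=1": 1, "WNT=0,RA=0": 1, "WNT=1,RA=1": 1, "WNT=1,RA=0": 1}
    },
    {
      "id": "i",
      "label": "HAND2 KO (no right ventricle)",
      "perturbations": [{"node": "HAND2", "mode": "ko"}],
      "expected": {"WNT=0,RA=1": 1, "WNT=0,RA=0": 1, "WNT=1,RA=1": 1, "WNT=1,RA=0": 0}
    },
    {
      "id": "ii",
      "label": "COUP-TFII KO (no atrial cardiomyocytes)",
      "perturbations": [{"node": "NR2F2", "mode": "ko"}],
      "expected": {"WNT=0,RA=1": 0, "WNT=0,RA=0": 1, "WNT=1,RA=1": 0, "WNT=1,RA=0": 1}
    },
    {
      "id": "iii",
      "label": "TBX5 KO (no atrial cardiomyocytes)",
      "perturbations": [{"node": "TBX5", "mode": "ko"}],
      "expected": {"WNT=0,RA=1": 0, "WNT=0,RA=0": 1, "WNT=1,RA=1": 0, "WNT=1,RA=0": 1}
    },
    {
      "id": "iv",
      "label": "NKX2-5 KO (no left ventricle)",
      "perturbations": [{"node": "NKX2_5", "mode": "ko"}],
      "expected": {"WNT=0,RA=1": 1, "WNT=0,RA=0": 0, "WNT=1,RA=1": 1, "WNT=1,RA=0": 1}
    },
    {
      "id": "v",
      "label": "NKX2-5 + HAND2 KO (no ventricle)",
      "perturbations": [{"node": "NKX2_5", "mode": "ko"}, {"node": "HAND2", "mode": "ko"}],
      "expected": {"WNT=0,RA=1": 1, "WNT=0,RA=0": 0, "WNT=1,RA=1": 1, "WNT=1,RA=0": 0}
    },
    {
      "id": "vi",
      "label": "HEY2 KO (abnormal left ventricle)",
      "perturbations": [{"node": "HEY2", "mode": "ko"}],
      "expected": {"WNT=0,RA=1": 1, "WNT=0,RA=0": 0, "WNT=1,RA=1": 1, "WNT=1,RA=0": 1}
    },
    {
      "id": "vii",
      "label": "HEY2 overexpression (represses atrial genes)",
      "perturbations": [{"node": "HEY2", "mode": "oe"}],
      "expected": {"WNT=0,RA=1": 0, "WNT=0,RA=0": 1, "WNT=1,RA=1": 0, "WNT=1,RA=0": 1}
    }
  ]
}
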