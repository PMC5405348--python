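{
  "description": "Manually designed motifs (MDMs) for aliphatic and aromatic nitrilases, PROSITE-like dash syntax. catalytic maps triad residue -> 1-based element index.",
  "patterns": [
    {"id": "ali-1", "class_label": "aliphatic", "pattern": "[FL]-[ILV]-[AV]-F-P-E-[VT]-[FW]-[IL]-P-[GY]-Y-P-[WY]", "catalytic": {"E": 6}},
    {"id": "ali-2", "class_label": "aliphatic", "pattern": "R-R-K-[LI]-[KRI]-[PA]-T-[HY]-[VAH]-E-R", "catalytic": {"K": 3}},
    {"id": "ali-3", "class_label": "aliphatic", "pattern": "C-W-E-H-[FLX]-[NQ]-[PT]-L", "catalytic": {"C": 1}},
    {"id": "ali-4", "class_label": "aliphatic", "pattern": "[VA]-A-X-[AV]-Q-[AI]-X-P-[VA]-X-[LF]-[SD]", "catalytic": {}},
    {"id": "aro-1", "class_label": "aromatic", "pattern": "[ALV]-[LV]-[FLM]-P-E-[AS]-[FLV]-[LV]-[AGP]-[AG]-Y-P", "catalytic": {"E": 5}},
    {"id": "aro-2", "class_label": "aromatic", "pattern": "[AGN]-[KR]-H-R-K-L-[MK]-P-T-[AGN]-X-E-R", "catalytic": {"K": 5}},
    {"id": "aro-3", "class_label": "aromatic", "pattern": "C-W-E-N-[HY]-M-P-[LM]-[AL]-R-X-X-[ML]-Y", "catalytic": {"C": 1}},
    {"id": "aro-4", "class_label": "aromatic", "pattern": "A-X-E-G-R-C-[FW]-V-[LIV]", "catalytic": {}}
  ]
}
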