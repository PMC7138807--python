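{
  "description": "Published summary statistics of the 21-site China maize-field 16S survey; used as reference inputs for desk-checkable arithmetic.",
  "n_samples": 21,
  "total_sequences": 613504,
  "min_depth": 18844,
  "max_depth": 36891,
  "n_otus": 5318,
  "n_core_otus": 421,
  "dominant_phylum_percent": {
    "Proteobacteria": 43.1,
    "Actinobacteria": 24.4,
    "Acidobacteria": 10.7,
    "Chloroflexi": 6.0,
    "Gemmatimonadetes": 5.5
  },
  "otu_network": {"n_nodes": 5312, "n_edges": 181157, "apl": 3.237, "diameter": 4.401, "clustering": 0.162},
  "er_null": {"apl": 2.398, "clustering": 0.0128, "diameter": 3},
  "genus_network": {"n_nodes": 184, "n_edges": 639},
  "ddr_slope": -0.043,
  "core_contribution_percent": {"mean": 64.45, "min": 39.32, "max": 81.83}
}
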