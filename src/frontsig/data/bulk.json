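{
  "schema_version": 1,
  "region": "bulk",
  "n_g": 5,
  "n_f": 3,
  "intercept": null,
  "standardization": null,
  "modules": [
    {
      "name": "INFLAMMATORY_RESPONSE_up",
      "source_set": "INFLAMMATORY_RESPONSE_up",
      "genes": ["EBI3", "KCNMB3", "TLR2", "IRF1", "TACR3"],
      "directions": [1, 1, 1, -1, -1],
      "coefficient": 1.1161,
      "train_auc": null
    },
    {
      "name": "IL6_JAK_STAT3_SIGNALING_up",
      "source_set": "IL6_JAK_STAT3_SIGNALING_up",
      "genes": ["EBI3", "HAX1", "TLR2", "IRF1", "CXCL9"],
      "directions": [1, 1, 1, -1, -1],
      "coefficient": -0.1483,
      "train_auc": null
    },
    {
      "name": "APICAL_JUNCTION_up",
      "source_set": "APICAL_JUNCTION_up",
      "genes": ["CLDN4", "LAYN", "ITGA9", "NRAP", "CADM3"],
      "directions": [1, 1, 1, 1, 1],
      "coefficient": 0.6747,
      "train_auc": null
    }
  ],
  "metadata": {
    "description": "Published bulk-tumor early-relapse signature. Uncalibrated linear score: no intercept was published."
  }
}
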