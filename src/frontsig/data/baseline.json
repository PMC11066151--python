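{
  "schema_version": 1,
  "region": "baseline",
  "n_g": 4,
  "n_f": 5,
  "intercept": null,
  "standardization": null,
  "modules": [
    {
      "name": "INTERFERON_GAMMA_RESPONSE_up1",
      "source_set": "INTERFERON_GAMMA_RESPONSE_up",
      "genes": ["LATS2", "IRF1", "TRIM14", "APOL6"],
      "directions": [1, -1, -1, -1],
      "coefficient": 1.0545,
      "train_auc": null
    },
    {
      "name": "INTERFERON_GAMMA_RESPONSE_up2",
      "source_set": "INTERFERON_GAMMA_RESPONSE_up",
      "genes": ["LATS2", "CXCL9", "TRIM14", "APOL6"],
      "directions": [1, -1, -1, -1],
      "coefficient": -0.7575,
      "train_auc": null
    },
    {
      "name": "INTERFERON_GAMMA_RESPONSE_up3",
      "source_set": "INTERFERON_GAMMA_RESPONSE_up",
      "genes": ["LATS2", "IRF1", "TRIM14", "CXCL9"],
      "directions": [1, -1, -1, -1],
      "coefficient": 2.0305,
      "train_auc": null
    },
    {
      "name": "TNFA_SIGNALING_VIA_NFKB_up1",
      "source_set": "TNFA_SIGNALING_VIA_NFKB_up",
      "genes": ["DUSP1", "LAMB3", "IRF1", "SLC2A6"],
      "directions": [1, 1, -1, -1],
      "coefficient": 1.8225,
      "train_auc": null
    },
    {
      "name": "TNFA_SIGNALING_VIA_NFKB_up2",
      "source_set": "TNFA_SIGNALING_VIA_NFKB_up",
      "genes": ["DUSP1", "JUN", "IRF1", "SLC2A6"],
      "directions": [1, 1, -1, -1],
      "coefficient": -0.9185,
      "train_auc": null
    }
  ],
  "metadata": {
    "description": "Published baseline early-relapse signature (bulk tumor profiles restricted to the cross-platform gene intersection). Uncalibrated linear score: no intercept was published."
  }
}
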