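{
  "schema_version": 1,
  "region": "invasion_front",
  "n_g": 4,
  "n_f": 3,
  "intercept": null,
  "standardization": null,
  "modules": [
    {
      "name": "APICAL_JUNCTION_up",
      "source_set": "APICAL_JUNCTION_up",
      "genes": ["VCAN", "CLDN19", "PTEN", "CDH1"],
      "directions": [1, 1, 1, 1],
      "coefficient": 0.1652,
      "train_auc": null
    },
    {
      "name": "KRAS_SIGNALING_up",
      "source_set": "KRAS_SIGNALING_up",
      "genes": ["GABRA3", "APOD", "JUP", "TMEM100"],
      "directions": [1, 1, 1, -1],
      "coefficient": 0.1527,
      "train_auc": null
    },
    {
      "name": "HEME_METABOLISM_up",
      "source_set": "HEME_METABOLISM_up",
      "genes": ["EZH1", "CCDC28A", "FBXO9", "SLC6A8"],
      "directions": [1, 1, 1, 1],
      "coefficient": 0.0915,
      "train_auc": null
    }
  ],
  "metadata": {
    "description": "Published invasion-front early-relapse signature. Uncalibrated linear score: no intercept was published."
  }
}
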