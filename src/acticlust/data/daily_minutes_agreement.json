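{
  "comment": "Reference free-living daily-minutes summary (N=8): model cluster groups vs thigh-monitor criterion categories.",
  "categories": {
    "sedentary": {
      "model_clusters": ["A", "B", "C", "D", "E", "F"],
      "model_mean": 1024.90, "model_sd": 67.38,
      "criterion": "sedentary", "criterion_mean": 1117.54, "criterion_sd": 64.86
    },
    "stand_step": {
      "model_clusters": ["G", "H"],
      "model_mean": 293.19, "model_sd": 63.59,
      "criterion": "stand/step", "criterion_mean": 280.98, "criterion_sd": 65.22
    },
    "high_step": {
      "model_clusters": ["I", "J"],
      "model_mean": 121.17, "model_sd": 38.23,
      "criterion": "high step", "criterion_mean": 41.49, "criterion_sd": 32.19
    }
  }
}
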