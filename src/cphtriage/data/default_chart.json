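{
  "predictors": [
    {
      "name": "oxygen_treatment",
      "field": "oxygen_treatment",
      "cutoff": null,
      "direction": "flag",
      "weight": 4
    },
    {
      "name": "sbp_low",
      "field": "sbp",
      "cutoff": 100.0,
      "direction": "below",
      "weight": 3
    },
    {
      "name": "hr_high",
      "field": "hr",
      "cutoff": 110.0,
      "direction": "above",
      "weight": 2
    },
    {
      "name": "rr_high",
      "field": "rr",
      "cutoff": 22.0,
      "direction": "above",
      "weight": 3
    },
    {
      "name": "spo2_low",
      "field": "spo2",
      "cutoff": 94.0,
      "direction": "below",
      "weight": 2
    }
  ],
  "thresholds": [
    1,
    4,
    5
  ],
  "meta": {
    "thresholds_calibrated_on": "default synthetic cohort",
    "calibration_n": 100000,
    "calibration_seed": 20160,
    "category_mortality_pct": [
      2.0448,
      4.7841,
      8.2107,
      16.1356
    ]
  }
}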