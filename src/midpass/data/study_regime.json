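{
  "n_patients": 50,
  "baseline": {
    "nrs": [
      6.5,
      1.7
    ],
    "prwhe_pain": [
      34.2,
      6.8
    ],
    "prwhe_function": [
      30.0,
      7.9
    ]
  },
  "recovery_curve": {
    "post_splint_6wk": 0.1,
    "m3": 0.45,
    "m6": 0.55,
    "m9": 0.6,
    "m12": 0.65
  },
  "improvement_gain": {
    "nrs": 6.5,
    "prwhe_pain": 29.0,
    "prwhe_function": 27.0
  },
  "noise_sd": {
    "nrs": 0.9,
    "prwhe_pain": 3.0,
    "prwhe_function": 3.5
  },
  "patient_sd": 0.25,
  "baseline_correlation": 0.5,
  "grc_thresholds": [
    -0.35,
    -0.05,
    0.38461538461538464,
    0.55
  ],
  "anchor_noise_sd": 0.12,
  "pass_location": {
    "nrs": 2.5,
    "prwhe_pain": 15.0,
    "prwhe_function": 11.0
  },
  "pass_scale": 0.1,
  "missing_rate": 0.0,
  "include_items": false,
  "seed": 0
}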