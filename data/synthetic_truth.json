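{
  "nodes": [
    "dT",
    "Treatment",
    "Growth",
    "dANB",
    "dIMPA",
    "dPPPM",
    "dCoA",
    "dGoPg",
    "dCoGo"
  ],
  "sample_size": 0,
  "locals": [
    {
      "node": "dT",
      "parents": [],
      "intercept": 6.5,
      "coefficients": [],
      "residual_sd": 1.4433756729740645
    },
    {
      "node": "Treatment",
      "parents": [],
      "intercept": 0.46153846153846156,
      "coefficients": [],
      "residual_sd": 0.4985185152621431
    },
    {
      "node": "Growth",
      "parents": [
        "dT"
      ],
      "intercept": 0.8,
      "coefficients": [
        -0.05
      ],
      "residual_sd": 0.45
    },
    {
      "node": "dANB",
      "parents": [
        "Growth",
        "Treatment",
        "dT"
      ],
      "intercept": 0.2,
      "coefficients": [
        1.2,
        1.5,
        -0.35
      ],
      "residual_sd": 1.0
    },
    {
      "node": "dIMPA",
      "parents": [
        "dANB",
        "dPPPM"
      ],
      "intercept": -0.5,
      "coefficients": [
        1.2,
        0.5
      ],
      "residual_sd": 2.5
    },
    {
      "node": "dPPPM",
      "parents": [
        "dCoGo"
      ],
      "intercept": 0.8,
      "coefficients": [
        -0.4
      ],
      "residual_sd": 1.2
    },
    {
      "node": "dCoA",
      "parents": [
        "Treatment",
        "dT"
      ],
      "intercept": 0.5,
      "coefficients": [
        1.5,
        0.9
      ],
      "residual_sd": 1.2
    },
    {
      "node": "dGoPg",
      "parents": [
        "dCoA",
        "dT"
      ],
      "intercept": 1.0,
      "coefficients": [
        0.6,
        0.9
      ],
      "residual_sd": 1.5
    },
    {
      "node": "dCoGo",
      "parents": [
        "Growth",
        "dCoA",
        "dT"
      ],
      "intercept": 0.5,
      "coefficients": [
        -1.0,
        0.4,
        0.6
      ],
      "residual_sd": 1.2
    }
  ]
}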