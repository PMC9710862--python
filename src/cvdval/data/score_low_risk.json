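{
  "model": "SCORE (low-risk European regions), TC/HDL-ratio variant",
  "version": "2024.1",
  "source": "Weibull baseline parameters and log-hazard coefficients transcribed from the 2003 SCORE project publication (low-risk equations, cholesterol-ratio variant). Verify against the original before any clinical use.",
  "centering": {
    "ratio": 5.0,
    "sbp": 120.0
  },
  "ra_multiplier": 1.0,
  "params": {
    "male": {
      "chd": {
        "p": 4.71,
        "alpha": -22.1,
        "beta_ratio": 0.088,
        "beta_sbp": 0.018,
        "beta_smoker": 0.71
      },
      "non_chd": {
        "p": 5.64,
        "alpha": -26.7,
        "beta_ratio": 0.095,
        "beta_sbp": 0.022,
        "beta_smoker": 0.63
      }
    },
    "female": {
      "chd": {
        "p": 6.36,
        "alpha": -29.8,
        "beta_ratio": 0.088,
        "beta_sbp": 0.018,
        "beta_smoker": 0.71
      },
      "non_chd": {
        "p": 6.62,
        "alpha": -31.0,
        "beta_ratio": 0.095,
        "beta_sbp": 0.022,
        "beta_smoker": 0.63
      }
    }
  }
}
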