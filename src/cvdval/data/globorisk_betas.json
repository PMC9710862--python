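{
  "model": "Globorisk fatal+non-fatal CVD, laboratory and office variants",
  "version": "2024.1",
  "source": "PLACEHOLDER PROVENANCE: coefficient structure (main effects with age interactions) follows the Globorisk publications; values are representative transcriptions pending verification against the originals. Recalibration targets and mean levels below are synthetic Netherlands-like inputs, as the national tables are not redistributable.",
  "lab": {
    "age_center": 60.0,
    "betas": {
      "sbp": {
        "main": 0.022,
        "age_interaction": -0.0002
      },
      "tc": {
        "main": 0.22,
        "age_interaction": -0.004
      },
      "smoker": {
        "main": 0.6,
        "age_interaction": -0.012
      },
      "diabetes": {
        "main": 0.7,
        "age_interaction": -0.01
      }
    }
  },
  "office": {
    "age_center": 60.0,
    "betas": {
      "sbp": {
        "main": 0.022,
        "age_interaction": -0.0002
      },
      "bmi": {
        "main": 0.045,
        "age_interaction": -0.0006
      },
      "smoker": {
        "main": 0.65,
        "age_interaction": -0.012
      }
    }
  }
}
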