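{
  "model": "SCORE-FNF fatal-to-total multipliers (EPIC-NL style)",
  "version": "2024.1",
  "source": "PLACEHOLDER PROVENANCE: age/sex multipliers of this structure are defined in the Dutch CVRM guideline from EPIC-NL data; the exact published values were not available for transcription, so these are representative values (non-fatal burden relative to fatal falls with age and is larger in women). Replace from the guideline before any clinical use.",
  "bands": [
    {
      "sex": "male",
      "age_lo": 40,
      "age_hi": 49,
      "multiplier": 4.0
    },
    {
      "sex": "male",
      "age_lo": 50,
      "age_hi": 59,
      "multiplier": 3.0
    },
    {
      "sex": "male",
      "age_lo": 60,
      "age_hi": 70,
      "multiplier": 2.3
    },
    {
      "sex": "female",
      "age_lo": 40,
      "age_hi": 49,
      "multiplier": 6.0
    },
    {
      "sex": "female",
      "age_lo": 50,
      "age_hi": 59,
      "multiplier": 4.0
    },
    {
      "sex": "female",
      "age_lo": 60,
      "age_hi": 70,
      "multiplier": 3.0
    }
  ]
}
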