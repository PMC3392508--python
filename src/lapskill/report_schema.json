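{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "lapskill validity report",
  "type": "object",
  "required": ["map_comparison", "hotelling", "wald_table", "classification", "model", "provenance"],
  "properties": {
    "map_comparison": {
      "type": "array",
      "minItems": 9,
      "maxItems": 9,
      "items": {
        "type": "object",
        "required": ["map", "novice_n", "novice_mean", "novice_sd", "expert_n", "expert_mean", "expert_sd", "statistic", "df", "p", "p_display"],
        "properties": {
          "map": {"type": "string"},
          "p": {"type": "number", "minimum": 0, "maximum": 1}
        }
      }
    },
    "hotelling": {
      "type": "object",
      "required": ["statistic", "statistic_name", "df", "p", "method"],
      "properties": {"p": {"type": "number", "minimum": 0, "maximum": 1}}
    },
    "wald_table": {
      "type": "array",
      "minItems": 9,
      "maxItems": 9,
      "items": {
        "type": "object",
        "required": ["map", "beta", "se", "wald", "p", "degenerate"]
      }
    },
    "classification": {
      "type": "object",
      "required": ["correct_novice", "total_novice", "correct_expert", "total_expert", "pct_novice", "pct_expert", "pct_overall"]
    },
    "model": {
      "type": "object",
      "required": ["beta", "se", "ridge", "converged", "scaling"]
    },
    "likert": {"type": ["array", "null"]},
    "provenance": {
      "type": "object",
      "required": ["package", "version", "config", "n_novice", "n_expert", "warnings"]
    }
  }
}
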