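{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Drug-pair synergy heatmap payload",
  "type": "object",
  "required": ["drugs", "cell_lines", "matrix", "details"],
  "properties": {
    "drugs": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name"],
        "properties": {
          "name": {"type": "string"},
          "target": {"type": ["string", "null"]}
        }
      }
    },
    "cell_lines": {"type": "array", "items": {"type": "string"}},
    "matrix": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["i", "j", "drug1", "drug2", "absolute_score", "specificity_score"],
        "properties": {
          "i": {"type": "integer", "minimum": 0},
          "j": {"type": "integer", "minimum": 1},
          "drug1": {"type": "string"},
          "drug2": {"type": "string"},
          "absolute_score": {"type": "integer", "minimum": 0},
          "specificity_score": {"type": "number"}
        }
      }
    },
    "details": {
      "type": "object",
      "additionalProperties": {
        "type": "array",
        "items": {
          "type": "object",
          "required": [
            "cell_line", "dose_level", "observed_v", "observed_se",
            "expected_v", "expected_se", "singlets", "synergistic", "antagonistic"
          ],
          "properties": {
            "cell_line": {"type": "string"},
            "dose_level": {"enum": ["high", "low"]},
            "observed_v": {"type": "number"},
            "observed_se": {"type": "number", "minimum": 0},
            "expected_v": {"type": "number"},
            "expected_se": {"type": "number", "minimum": 0},
            "singlets": {
              "type": "array",
              "minItems": 2,
              "maxItems": 2,
              "items": {
                "type": "object",
                "required": ["drug", "v_hat", "se_v"],
                "properties": {
                  "drug": {"type": "string"},
                  "v_hat": {"type": "number"},
                  "se_v": {"type": "number", "minimum": 0}
                }
              }
            },
            "synergistic": {"type": "boolean"},
            "antagonistic": {"type": "boolean"}
          }
        }
      }
    }
  }
}
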