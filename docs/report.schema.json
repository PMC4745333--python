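{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "greyhrv analysis report",
  "type": "object",
  "required": ["generator", "sections"],
  "properties": {
    "generator": {"const": "greyhrv"},
    "sections": {"type": "array", "items": {"enum": ["comparison", "cross_validation", "weekly_summary"]}},
    "comparison": {
      "type": "object",
      "required": ["before", "after", "rank_before", "rank_after"],
      "properties": {
        "before": {"$ref": "#/$defs/weighting"},
        "after": {"$ref": "#/$defs/weighting"},
        "weight_change": {"type": "object", "additionalProperties": {"type": "number"}},
        "rank_before": {"$ref": "#/$defs/ranking"},
        "rank_after": {"$ref": "#/$defs/ranking"}
      }
    },
    "cross_validation": {
      "type": "object",
      "required": ["seed", "sizes", "entries"],
      "properties": {
        "seed": {"type": "integer"},
        "sizes": {"type": "array", "items": {"type": "integer"}},
        "entries": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["size", "subjects", "before", "after"],
            "properties": {
              "size": {"type": "integer"},
              "subjects": {"type": "array", "items": {"type": "string"}},
              "before": {"$ref": "#/$defs/weighting"},
              "after": {"$ref": "#/$defs/weighting"}
            }
          }
        }
      }
    },
    "weekly_summary": {
      "type": "object",
      "required": ["means"],
      "properties": {
        "means": {"type": "object", "additionalProperties": {"type": "object", "additionalProperties": {"type": "number"}}},
        "sds": {"type": "object"},
        "psi_reduction_candidates_pct": {"type": "object", "additionalProperties": {"type": "number"}}
      }
    },
    "provenance": {
      "type": "object",
      "properties": {
        "input": {"type": "string"},
        "seed": {"type": "integer"},
        "version": {"type": "string"}
      }
    }
  },
  "$defs": {
    "ranking": {"type": "array", "items": {"enum": ["TP", "VLF", "LF", "HF"]}},
    "weighting": {
      "type": "object",
      "required": ["weights", "ranking", "n_samples"],
      "properties": {
        "weights": {"type": "object", "additionalProperties": {"type": "number"}},
        "weights_signed": {"type": "object", "additionalProperties": {"type": "number"}},
        "mean_weighting": {"type": "number"},
        "ranking": {"$ref": "#/$defs/ranking"},
        "residual_norm": {"type": "number"},
        "n_samples": {"type": "integer"}
      }
    }
  }
}
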