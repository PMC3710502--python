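{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Scene configuration document",
  "type": "object",
  "additionalProperties": false,
  "properties": {
    "settings": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "axis_scale": {
          "type": "array", "minItems": 3, "maxItems": 3,
          "items": {"type": "number", "exclusiveMinimum": 0}
        },
        "raw_opacity": {"type": "number", "exclusiveMinimum": 0, "maximum": 1},
        "layer_opacity": {"type": "number", "exclusiveMinimum": 0, "maximum": 1},
        "raw_size": {"type": "number", "exclusiveMinimum": 0},
        "layer_size": {"type": "number", "exclusiveMinimum": 0},
        "center": {"type": "boolean"}
      }
    },
    "worlds": {
      "type": "array",
      "maxItems": 4,
      "items": {
        "type": "object",
        "additionalProperties": false,
        "properties": {
          "datasets": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["path"],
              "additionalProperties": false,
              "properties": {
                "path": {"type": "string"},
                "name": {"type": "string"},
                "family_hint": {"enum": ["dataset", "information"]},
                "layer": {
                  "type": "object",
                  "required": ["path"],
                  "additionalProperties": false,
                  "properties": {
                    "path": {"type": "string"},
                    "index": {"type": "integer", "minimum": 0},
                    "family_hint": {"enum": ["dataset", "information"]}
                  }
                },
                "hidden_classes": {
                  "type": "array", "items": {"type": "integer", "minimum": 0}
                },
                "colours": {
                  "type": "object",
                  "additionalProperties": {
                    "type": "array", "minItems": 3, "maxItems": 3,
                    "items": {"type": "number", "minimum": 0, "maximum": 1}
                  }
                }
              }
            }
          }
        }
      }
    }
  }
}
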