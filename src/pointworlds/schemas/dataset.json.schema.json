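{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Dataset file (JSON dialect)",
  "type": "object",
  "required": ["dataset"],
  "additionalProperties": false,
  "properties": {
    "dataset": {
      "type": "object",
      "required": ["points"],
      "additionalProperties": false,
      "properties": {
        "name": {"type": "string"},
        "chain": {"type": "boolean", "default": false},
        "points": {
          "type": "array",
          "minItems": 1,
          "items": {
            "type": "array",
            "minItems": 3,
            "maxItems": 3,
            "items": {"type": "number"}
          }
        }
      }
    }
  }
}
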