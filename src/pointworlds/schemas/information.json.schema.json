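{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Information-layer file (JSON dialect)",
  "type": "object",
  "required": ["information"],
  "additionalProperties": false,
  "properties": {
    "information": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["numClass", "values"],
        "additionalProperties": false,
        "properties": {
          "name": {"type": "string"},
          "numClass": {"type": "integer", "minimum": 1},
          "labels": {"type": "array", "items": {"type": "string"}},
          "values": {
            "type": "array",
            "minItems": 1,
            "items": {"type": "integer"}
          }
        }
      }
    }
  }
}
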