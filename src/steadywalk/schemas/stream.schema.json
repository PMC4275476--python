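{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "Skeleton stream (JSONL)",
  "description": "Line-delimited JSON: the first line matches 'header', every later line matches 'frame'. Timestamps are strictly increasing seconds; coordinates are meters.",
  "definitions": {
    "header": {
      "type": "object",
      "properties": {
        "fps": {"type": "number", "exclusiveMinimum": 0},
        "subject_height": {"type": "number"},
        "source": {"type": "string"}
      }
    },
    "frame": {
      "type": "object",
      "required": ["t", "joints"],
      "properties": {
        "t": {"type": "number", "minimum": 0},
        "joints": {
          "type": "object",
          "minProperties": 20,
          "maxProperties": 20,
          "additionalProperties": {
            "type": "array", "items": {"type": "number"},
            "minItems": 3, "maxItems": 3
          }
        }
      }
    }
  }
}
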