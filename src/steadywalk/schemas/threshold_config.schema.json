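{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "Threshold configuration",
  "type": "object",
  "properties": {
    "strictness": {"type": "number", "exclusiveMinimum": 0},
    "overrides": {"type": "object", "additionalProperties": {"type": "number", "exclusiveMinimum": 0}},
    "included_parts": {"type": "array", "items": {"type": "string"}, "minItems": 1},
    "balance_epsilon": {"type": "number", "exclusiveMinimum": 0},
    "debounce_frames": {"type": "integer", "minimum": 1}
  }
}
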