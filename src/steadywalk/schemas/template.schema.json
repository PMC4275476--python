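{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "Posture template",
  "type": "object",
  "required": ["name", "rules"],
  "properties": {
    "name": {"type": "string"},
    "rules": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "joint_a", "joint_b", "axis", "base_epsilon", "body_part"],
        "properties": {
          "id": {"type": "string"},
          "joint_a": {"type": "string"},
          "joint_b": {"type": "string"},
          "axis": {"enum": ["x", "y"]},
          "base_epsilon": {"type": "number", "exclusiveMinimum": 0},
          "body_part": {"type": "string"}
        }
      }
    }
  }
}
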