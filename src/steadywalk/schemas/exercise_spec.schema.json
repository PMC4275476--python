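{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "Exercise specification",
  "type": "object",
  "properties": {
    "course_length": {"type": "number", "exclusiveMinimum": 0},
    "start_z": {"type": "number"},
    "finish_z": {"type": "number"},
    "corridor_center_x": {"type": "number"},
    "corridor_half_width": {"type": "number", "exclusiveMinimum": 0},
    "hold_seconds": {"type": "number", "exclusiveMinimum": 0},
    "start_zone_tolerance": {"type": "number", "exclusiveMinimum": 0},
    "direction": {"enum": ["forward", "backward"]}
  }
}
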