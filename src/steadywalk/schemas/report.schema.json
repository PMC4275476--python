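{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "Session report",
  "type": "object",
  "required": ["session_id", "patient_id", "attempts", "totals"],
  "properties": {
    "session_id": {"type": "string"},
    "patient_id": {"type": "string"},
    "attempts": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["index", "success", "error_events", "duration", "conclusions"],
        "properties": {
          "index": {"type": "integer", "minimum": 1},
          "success": {"type": "boolean"},
          "error_events": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["fault_id", "start_t", "end_t"]
            }
          },
          "duration": {"type": "number", "minimum": 0},
          "conclusions": {"type": "array", "items": {"type": "string"}},
          "complete": {"type": "boolean"}
        }
      }
    },
    "totals": {
      "type": "object",
      "required": ["attempts", "successes", "total_errors", "errors_by_fault"]
    },
    "durations": {"type": "array", "items": {"type": "number"}},
    "mean_duration": {"type": "number"},
    "config_snapshot": {"type": "object"}
  }
}
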