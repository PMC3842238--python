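{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "paleofam inference report",
  "type": "object",
  "required": ["provenance", "report"],
  "properties": {
    "provenance": {
      "type": "object",
      "required": ["tool", "version", "config", "inputs"],
      "properties": {
        "tool": {"type": "string"},
        "version": {"type": "string"},
        "config": {"type": "object"},
        "inputs": {"type": "object"}
      }
    },
    "report": {
      "type": "object",
      "required": [
        "origin",
        "origin_rank",
        "family_absent",
        "hgt_candidates",
        "gains",
        "losses",
        "complete_losses"
      ],
      "properties": {
        "origin": {"type": ["string", "null"]},
        "origin_rank": {"type": ["string", "null"]},
        "family_absent": {"type": "boolean"},
        "hgt_candidates": {"type": "array", "items": {"type": "string"}},
        "gains": {"type": "array"},
        "losses": {"type": "array"},
        "complete_losses": {"type": "array"}
      }
    }
  }
}
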