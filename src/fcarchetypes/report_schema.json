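{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "fcarchetypes run report",
  "type": "object",
  "required": ["config_hash", "seed", "stage_seeds", "stages", "status"],
  "properties": {
    "config_hash": {"type": "string"},
    "seed": {"type": "integer"},
    "stage_seeds": {
      "type": "object",
      "additionalProperties": {"type": "integer"}
    },
    "status": {"type": "string", "enum": ["ok", "failed"]},
    "failed_stage": {"type": ["string", "null"]},
    "diagnostic": {"type": ["string", "null"]},
    "stages": {
      "type": "object",
      "properties": {
        "reduce": {"type": "object"},
        "tune": {"type": "object"},
        "consensus": {"type": "object"},
        "nullcheck": {"type": "object"},
        "associate": {"type": "object"},
        "degeneracy": {"type": "object"}
      }
    }
  }
}
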