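{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "genotiler compilation report",
  "type": "object",
  "required": ["schema", "stage", "solutions", "counters"],
  "properties": {
    "schema": {"const": "genotiler-report/1"},
    "stage": {"enum": ["exhaustive", "evolutionary"]},
    "seed": {"type": ["integer", "null"]},
    "counters": {
      "type": "object",
      "required": ["candidates_examined", "agent_rejections", "unify_nodes",
                   "ga_evaluations", "effort"],
      "additionalProperties": {"type": "integer"}
    },
    "population_size": {"type": "integer"},
    "survivors": {"type": "integer"},
    "generations_run": {"type": "integer"},
    "diagnosis": {"type": ["string", "null"]},
    "solutions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["components", "substitution", "derivation", "assembly"],
        "properties": {
          "components": {"type": "array", "items": {"type": "string"}},
          "substitution": {"type": "object", "additionalProperties": {"type": "string"}},
          "derivation": {"type": "array", "items": {"type": "string"}},
          "assembly": {"type": "string"}
        },
        "additionalProperties": false
      }
    }
  },
  "additionalProperties": false
}
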