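{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "genotiler component library",
  "type": "object",
  "required": ["schema", "components"],
  "properties": {
    "schema": {"const": "genotiler-library/1"},
    "components": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "program"],
        "properties": {
          "name": {"type": "string", "minLength": 1},
          "program": {"type": "string"},
          "description": {"type": "string"}
        },
        "additionalProperties": false
      }
    }
  },
  "additionalProperties": false
}
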