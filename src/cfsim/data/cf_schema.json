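{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Construction File",
  "description": "Normative JSON dialect for Construction Files: an ordered array of cloning steps plus full-structure sequence definitions. Extensions (ext5/ext3) are coding-strand strings; a '-' prefix marks a 3' protrusion.",
  "type": "object",
  "required": ["steps", "sequences"],
  "properties": {
    "steps": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["operation", "inputs", "product"],
        "properties": {
          "operation": {"enum": ["PCR", "Digest", "Ligate", "GoldenGate", "Gibson", "Transform"]},
          "inputs": {"type": "array", "items": {"type": "string"}, "minItems": 1},
          "product": {"type": "string", "minLength": 1},
          "product_size": {"type": "integer", "minimum": 1},
          "enzymes": {"type": "array", "items": {"type": "string"}, "minItems": 1},
          "fragSelect": {"type": "integer", "minimum": 0},
          "enzyme": {"type": "string"},
          "host": {"type": "string"},
          "antibiotic": {"type": "string"},
          "temperature": {"type": "number"}
        },
        "additionalProperties": false
      }
    },
    "sequences": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["sequence"],
        "properties": {
          "sequence": {"type": "string", "pattern": "^[ACGTRYSWKMBDHVNacgtryswkmbdhvn]*$"},
          "ext5": {"type": "string"},
          "ext3": {"type": "string"},
          "mod_ext5": {"enum": ["hydroxyl", "phosphate", null]},
          "mod_ext3": {"enum": ["hydroxyl", "phosphate", null]},
          "isDoubleStranded": {"type": "boolean"},
          "isCircular": {"type": "boolean"}
        },
        "additionalProperties": false
      }
    }
  },
  "additionalProperties": false
}
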