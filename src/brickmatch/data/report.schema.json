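{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Annotation report",
  "description": "Output of whole-map annotation: per-term distinct-instance counts, every instance with its bindings and focal element, and the term annotations derived from brick associations.",
  "type": "object",
  "required": ["map", "counts", "instances", "annotations"],
  "properties": {
    "map": {"type": "string"},
    "counts": {
      "type": "object",
      "additionalProperties": {"type": "integer", "minimum": 0}
    },
    "instances": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["brick", "elements"],
        "properties": {
          "brick": {"type": "string"},
          "elements": {"type": "array", "items": {"type": "string"}},
          "bindings": {"type": "object", "additionalProperties": {"type": "string"}},
          "focal": {"type": ["string", "null"]},
          "generic_only": {"type": "boolean"}
        }
      }
    },
    "annotations": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["brick", "term", "relation", "elements"],
        "properties": {
          "brick": {"type": "string"},
          "term": {"type": "string"},
          "relation": {"enum": ["main", "narrow", "alternate", "synonym", "broad"]},
          "elements": {"type": "array", "items": {"type": "string"}}
        }
      }
    }
  }
}
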