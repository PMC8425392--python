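{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Brick library",
  "description": "Template bricks, terms, categories and their relations. Label fields hold brick label patterns: $VAR$ variables, [..] optionals, LIT|LIT disjunctions, and whole-label {..} (repetition) or !..! (absence) modifiers.",
  "type": "object",
  "required": ["terms", "bricks"],
  "properties": {
    "name": {"type": "string"},
    "terms": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "name"],
        "properties": {
          "id": {"type": "string", "pattern": "^(GO|SBO|BKO):[0-9]{7}$"},
          "name": {"type": "string"},
          "source": {"enum": ["GO", "SBO", "BKO"]},
          "parents": {"type": "array", "items": {"type": "string"}},
          "alternate_ids": {"type": "array", "items": {"type": "string"}},
          "unrepresentable": {"type": "boolean"}
        }
      }
    },
    "categories": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "name"],
        "properties": {
          "id": {"type": "string"},
          "name": {"type": "string"},
          "supercategory": {"type": ["string", "null"]}
        }
      }
    },
    "bricks": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "language", "glyphs", "arcs", "associations"],
        "properties": {
          "id": {"type": "string", "pattern": "^BKO:[0-9]{7}$"},
          "language": {"enum": ["process description", "activity flow", "entity relationship"]},
          "name": {"type": "string"},
          "glyphs": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["id", "class"],
              "properties": {
                "id": {"type": "string"},
                "class": {"type": "string"},
                "label": {"type": "string"},
                "state": {
                  "type": ["object", "null"],
                  "properties": {
                    "value": {"type": "string"},
                    "variable": {"type": "string"}
                  }
                },
                "compartment": {"type": ["string", "null"]},
                "parent": {"type": ["string", "null"]}
              }
            }
          },
          "arcs": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["id", "class", "source", "target"],
              "properties": {
                "id": {"type": "string"},
                "class": {"type": "string"},
                "source": {"type": "string"},
                "target": {"type": "string"}
              }
            }
          },
          "associations": {
            "type": "array",
            "minItems": 1,
            "items": {
              "type": "object",
              "required": ["term", "relation"],
              "properties": {
                "term": {"type": "string"},
                "relation": {"enum": ["main", "narrow", "alternate", "synonym", "broad"]}
              }
            }
          },
          "categories": {"type": "array", "items": {"type": "string"}}
        }
      }
    },
    "subsumptions": {
      "type": "array",
      "items": {
        "type": "array",
        "prefixItems": [{"type": "string"}, {"type": "string"}],
        "minItems": 2,
        "maxItems": 2
      }
    },
    "generic_bricks": {"type": "array", "items": {"type": "string"}}
  }
}
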