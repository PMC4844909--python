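{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "Open-Annotation-style PDDI annotation document",
  "description": "Interchange format for one annotation source over a corpus of drug product label sections. Each annotation pairs a target (section id plus position selectors with the exact quoted text) with a typed body. Offsets are 0-based, half-open character positions into the section text.",
  "type": "object",
  "required": ["source_id", "source_kind", "annotations"],
  "properties": {
    "source_id": {"type": "string"},
    "source_kind": {"enum": ["reference", "nlp", "human"]},
    "provenance": {
      "type": "object",
      "description": "Free-form record of how the set was produced (e.g. the rule configuration of a preannotation run)."
    },
    "annotations": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "type", "target", "body"],
        "properties": {
          "id": {"type": "string"},
          "type": {"enum": ["drug_mention", "pddi_mention"]},
          "target": {
            "type": "object",
            "required": ["section_id"],
            "properties": {
              "section_id": {"type": "string"},
              "selector": {
                "type": "object",
                "description": "drug_mention target: character span with exact quote",
                "required": ["char_start", "char_end"],
                "properties": {
                  "char_start": {"type": "integer", "minimum": 0},
                  "char_end": {"type": "integer", "minimum": 1},
                  "exact": {"type": "string"}
                }
              },
              "selectors": {
                "type": "array",
                "description": "pddi_mention target: one selector per selected sentence",
                "items": {
                  "type": "object",
                  "required": ["sentence_index"],
                  "properties": {
                    "sentence_index": {"type": "integer", "minimum": 0},
                    "exact": {"type": "string"}
                  }
                }
              }
            }
          },
          "body": {
            "type": "object",
            "description": "drug_mention bodies carry entity_type/concept_id/normalized_ingredient_id; pddi_mention bodies carry precipitant, object, statement, modality. Unknown keys are preserved on read.",
            "properties": {
              "entity_type": {"enum": ["active_ingredient", "metabolite", "drug_product"]},
              "concept_id": {"type": "string"},
              "normalized_ingredient_id": {"type": "string"},
              "unmapped_product": {"type": "boolean"},
              "precipitant": {"$ref": "#/definitions/drug_reference"},
              "object": {"$ref": "#/definitions/drug_reference"},
              "statement": {"enum": ["quantitative", "qualitative"]},
              "modality": {"enum": ["positive", "negative"]}
            }
          }
        }
      }
    }
  },
  "definitions": {
    "drug_reference": {
      "type": "object",
      "required": ["normalized_ingredient_id", "entity_type"],
      "properties": {
        "normalized_ingredient_id": {"type": "string"},
        "entity_type": {"enum": ["active_ingredient", "metabolite", "drug_product"]}
      }
    }
  }
}
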