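{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "CIViC-API-shaped exchange document (frozen dialect)",
  "description": "One top-level object with variants, evidence_items and assertions arrays, as returned by the CIViC REST API and read from disk by mvldkit. Field names are snake_case and mirror the mvldkit.civic entity models, which are the enforced contract.",
  "type": "object",
  "required": ["variants", "evidence_items", "assertions"],
  "properties": {
    "variants": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["variant_id", "gene_symbol", "name", "chromosome", "start", "stop",
                     "reference_bases", "variant_bases", "reference_build",
                     "representative_transcript", "variant_types"],
        "properties": {
          "variant_id": {"type": "integer", "minimum": 1},
          "gene_symbol": {"type": "string"},
          "name": {"type": "string"},
          "chromosome": {"type": "string"},
          "start": {"type": "integer", "minimum": 1},
          "stop": {"type": "integer", "minimum": 1},
          "reference_bases": {"type": "string", "pattern": "^[ACGT]*$"},
          "variant_bases": {"type": "string", "pattern": "^[ACGT]*$"},
          "reference_build": {"enum": ["GRCh37", "GRCh38", "NCBI36"]},
          "representative_transcript": {"type": "string"},
          "variant_types": {"type": "array", "items": {"type": "string"}},
          "hgvs_expressions": {"type": "array", "items": {"type": "string"}},
          "allele_registry_id": {"type": ["string", "null"], "pattern": "^CA"}
        }
      }
    },
    "evidence_items": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["eid", "variant_id", "disease", "drugs", "evidence_type",
                     "evidence_direction", "clinical_significance", "evidence_level",
                     "rating", "pmid", "statement", "status"],
        "properties": {
          "eid": {"type": ["integer", "null"], "minimum": 1},
          "variant_id": {"type": ["integer", "null"], "minimum": 1},
          "disease": {
            "type": "object",
            "required": ["name"],
            "properties": {
              "name": {"type": "string"},
              "doid": {"type": ["string", "null"], "pattern": "^[0-9]+$"}
            }
          },
          "drugs": {"type": "array", "items": {"type": "string"}},
          "evidence_type": {"enum": ["Predictive", "Prognostic", "Diagnostic", "Predisposing"]},
          "evidence_direction": {"type": "string"},
          "clinical_significance": {"type": "string"},
          "evidence_level": {"enum": ["A", "B", "C", "D", "E"]},
          "rating": {"type": ["integer", "null"]},
          "pmid": {"type": "string"},
          "statement": {"type": "string"},
          "status": {"enum": ["submitted", "accepted", "rejected"]}
        }
      }
    },
    "assertions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["aid", "variant_id", "disease", "drugs", "assertion_type",
                     "amp_tier", "amp_level", "summary", "description",
                     "evidence_ids", "status"],
        "properties": {
          "aid": {"type": "integer", "minimum": 1},
          "variant_id": {"type": "integer", "minimum": 1},
          "disease": {
            "type": "object",
            "required": ["name"],
            "properties": {
              "name": {"type": "string"},
              "doid": {"type": ["string", "null"], "pattern": "^[0-9]+$"}
            }
          },
          "drugs": {"type": "array", "items": {"type": "string"}},
          "assertion_type": {"enum": ["Predictive", "Prognostic", "Diagnostic"]},
          "amp_tier": {"enum": ["Tier I", "Tier II"]},
          "amp_level": {"enum": ["Level A", "Level B", "Level C", "Level D"]},
          "clinical_significance": {"type": ["string", "null"]},
          "summary": {"type": "string"},
          "description": {"type": "string"},
          "evidence_ids": {"type": "array", "items": {"type": "integer"}},
          "status": {"enum": ["submitted", "accepted"]},
          "organization": {"type": ["string", "null"]}
        }
      }
    }
  }
}
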