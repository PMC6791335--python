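{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.org/bioscoop/record-set.schema.json",
  "title": "BioSCOOP record set",
  "description": "A UTF-8 JSON array of sample-donor exchange documents. Enum catalogues and patterns here mirror the validator's rule catalogue; cross-record rules (sampleId uniqueness) and cross-field rules (date ordering, derived-index consistency) are stated in the validator, not expressible as plain JSON Schema keywords.",
  "type": "array",
  "items": { "$ref": "#/$defs/record" },
  "$defs": {
    "isoDate": {
      "type": "string",
      "pattern": "^[0-9]{4}-[0-9]{1,2}-[0-9]{1,2}$"
    },
    "positiveNumber": {
      "type": "number",
      "exclusiveMinimum": 0
    },
    "record": {
      "type": "object",
      "required": ["donorId", "collectionId", "sampleId", "timestamp", "dataSource", "donor", "sample"],
      "properties": {
        "donorId": { "type": "string", "pattern": "\\S" },
        "collectionId": { "type": "string", "pattern": "\\S" },
        "sampleId": { "type": "string", "pattern": "\\S" },
        "timestamp": { "$ref": "#/$defs/isoDate" },
        "dataSource": {
          "enum": ["donor_questionnaire", "medical_record", "physical_measurement"]
        },
        "donor": { "$ref": "#/$defs/donor" },
        "anthropometry": { "$ref": "#/$defs/anthropometry" },
        "medicalEvents": {
          "type": "array",
          "items": { "$ref": "#/$defs/medicalEvent" }
        },
        "sample": { "$ref": "#/$defs/sample" }
      }
    },
    "donor": {
      "type": "object",
      "required": ["birthDate", "sex"],
      "properties": {
        "birthDate": { "$ref": "#/$defs/isoDate" },
        "birthPlace": { "type": "string" },
        "residencePlace": { "type": "string" },
        "sex": { "enum": ["male", "female", "other", "unknown"] },
        "ethnicOrigin": { "type": "string" },
        "skinTone": { "enum": ["I", "II", "III", "IV", "V", "VI"] },
        "hairColour": { "enum": ["black", "brown", "blond", "red", "grey", "other"] },
        "eyeColour": { "enum": ["brown", "blue", "green", "grey", "other"] },
        "bloodGroup": { "enum": ["A+", "A-", "B+", "B-", "AB+", "AB-", "O+", "O-", "unknown"] }
      }
    },
    "anthropometry": {
      "type": "object",
      "properties": {
        "heightCm": { "$ref": "#/$defs/positiveNumber" },
        "weightKg": { "$ref": "#/$defs/positiveNumber" },
        "waistCm": { "$ref": "#/$defs/positiveNumber" },
        "hipCm": { "$ref": "#/$defs/positiveNumber" },
        "whr": { "$ref": "#/$defs/positiveNumber" },
        "bmi": { "$ref": "#/$defs/positiveNumber" },
        "ci": { "$ref": "#/$defs/positiveNumber" },
        "extras": {
          "type": "object",
          "additionalProperties": { "$ref": "#/$defs/positiveNumber" }
        }
      }
    },
    "medicalEvent": {
      "type": "object",
      "required": ["icd10Code", "eventType"],
      "properties": {
        "icd10Code": { "type": "string", "pattern": "^[A-Z][0-9]{2}(\\.[0-9]{1,2})?$" },
        "eventType": { "enum": ["disease", "procedure"] },
        "eventDate": { "$ref": "#/$defs/isoDate" }
      }
    },
    "sample": {
      "type": "object",
      "required": ["materialForm"],
      "properties": {
        "materialForm": {
          "enum": ["whole_blood", "serum", "plasma", "dna", "rna", "saliva", "tissue", "urine", "other"]
        }
      }
    }
  }
}
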