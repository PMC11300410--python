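{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.org/decidenet/session.schema.json",
  "title": "decidenet session",
  "description": "One complete elicitation for a management unit. Structural schema only; content rules (selection limits, allocation sums, prediction-grid completeness) are checked by decidenet.session.validate_session.",
  "type": "object",
  "required": [
    "management_unit",
    "time_frame",
    "focal_user_group",
    "stakeholders",
    "objectives",
    "external_factors",
    "options",
    "predictions"
  ],
  "properties": {
    "management_unit": {"type": "string"},
    "time_frame": {"type": "string"},
    "focal_user_group": {"type": "string"},
    "stakeholders": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["group_id", "relative_importance"],
        "properties": {
          "group_id": {"type": "string"},
          "relative_importance": {"type": "integer", "minimum": 1, "maximum": 5}
        }
      }
    },
    "objectives": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["objective_id", "importance_by_stakeholder"],
        "properties": {
          "objective_id": {"type": "string"},
          "adapted_definition": {"type": "string"},
          "current_status": {"type": "string"},
          "desired_status": {"type": "string"},
          "importance_by_stakeholder": {
            "type": "object",
            "additionalProperties": {"type": "integer", "minimum": 1, "maximum": 5}
          }
        }
      }
    },
    "external_factors": {
      "type": "array",
      "maxItems": 2,
      "items": {
        "type": "object",
        "required": ["factor_id", "scenario_pair", "uncertainty"],
        "properties": {
          "factor_id": {"type": "string"},
          "scenario_pair": {
            "type": "array",
            "minItems": 2,
            "maxItems": 2,
            "items": {"type": "string"}
          },
          "uncertainty": {"type": "integer", "minimum": 1, "maximum": 5}
        }
      }
    },
    "options": {
      "type": "array",
      "minItems": 2,
      "maxItems": 2,
      "items": {
        "type": "object",
        "required": ["option_label", "resource_type", "allocations"],
        "properties": {
          "option_label": {"type": "string"},
          "resource_type": {"enum": ["time", "money"]},
          "allocations": {
            "type": "object",
            "minProperties": 2,
            "maxProperties": 4,
            "additionalProperties": {"type": "number", "minimum": 0}
          }
        }
      }
    },
    "predictions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["objective_id", "option_index", "scenario_assignment", "score"],
        "properties": {
          "objective_id": {"type": "string"},
          "option_index": {"enum": [1, 2]},
          "scenario_assignment": {
            "type": "object",
            "additionalProperties": {"type": "string"}
          },
          "score": {"type": "integer", "minimum": 1, "maximum": 5}
        }
      }
    },
    "metadata": {"type": "object"}
  }
}
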