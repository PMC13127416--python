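{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "adtcea model specification",
  "description": "Complete parameterization of a Markov cohort cost-effectiveness analysis: strategies (mixtures of arms), economics, shared mortality, run settings, and sensitivity-analysis declarations. YAML files with the same keys are equally accepted.",
  "type": "object",
  "required": ["strategies", "econ", "mortality"],
  "properties": {
    "horizon": {"type": "integer", "minimum": 1, "default": 15},
    "cycle_length": {"type": "number", "exclusiveMinimum": 0, "default": 1.0},
    "half_cycle_correction": {"type": "boolean", "default": true},
    "strategies": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["name", "components"],
        "properties": {
          "name": {"type": "string"},
          "components": {
            "type": "array",
            "minItems": 1,
            "items": {
              "type": "object",
              "required": ["weight", "arm"],
              "properties": {
                "weight": {"type": "number", "minimum": 0, "maximum": 1},
                "arm": {
                  "type": "object",
                  "required": ["id", "receives_adt", "p_metastasis"],
                  "properties": {
                    "id": {"type": "string"},
                    "receives_adt": {"type": "boolean"},
                    "p_metastasis": {
                      "type": "array",
                      "items": {"type": "number", "minimum": 0, "maximum": 1}
                    },
                    "upfront_cost": {"type": "number", "minimum": 0, "default": 0}
                  }
                }
              }
            }
          }
        }
      }
    },
    "econ": {
      "type": "object",
      "required": [
        "cost_metastatic", "cost_eol_cancer", "cost_eol_noncancer",
        "utility_on_adt", "utility_off_adt", "utility_metastatic"
      ],
      "properties": {
        "cost_metastatic": {"type": "number", "minimum": 0},
        "cost_eol_cancer": {"type": "number", "minimum": 0},
        "cost_eol_noncancer": {"type": "number", "minimum": 0},
        "utility_on_adt": {"type": "number", "minimum": 0, "maximum": 1},
        "utility_off_adt": {"type": "number", "minimum": 0, "maximum": 1},
        "utility_metastatic": {"type": "number", "minimum": 0, "maximum": 1},
        "discount_rate": {"type": "number", "minimum": 0, "default": 0.03},
        "wtp": {"type": "number", "minimum": 0, "default": 100000}
      }
    },
    "mortality": {
      "type": "object",
      "required": ["p_death_other", "p_death_metastatic_excess"],
      "properties": {
        "p_death_other": {
          "type": "array",
          "items": {"type": "number", "minimum": 0, "maximum": 1}
        },
        "p_death_metastatic_excess": {
          "type": "array",
          "items": {"type": "number", "minimum": 0, "maximum": 1}
        }
      }
    },
    "params": {
      "type": "object",
      "additionalProperties": {"type": "number"},
      "description": "Free scalar parameters addressable as params.<name> by DSA/PSA and derived rules."
    },
    "derived_params": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["target", "kind"],
        "properties": {
          "target": {"type": "string", "description": "Dotted parameter path."},
          "kind": {"enum": ["complement", "sum", "difference", "fill"]},
          "sources": {"type": "array", "items": {"type": "string"}}
        }
      }
    },
    "dsa_ranges": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["param_path", "low", "high"],
        "properties": {
          "param_path": {"type": "string"},
          "low": {"type": "number"},
          "high": {"type": "number"}
        }
      }
    },
    "psa_distributions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["param_path", "family", "base", "bound_low", "bound_high"],
        "properties": {
          "param_path": {"type": "string"},
          "family": {"enum": ["beta", "gamma", "uniform", "fixed"]},
          "base": {"type": "number"},
          "bound_low": {"type": "number"},
          "bound_high": {"type": "number"}
        }
      }
    }
  }
}
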