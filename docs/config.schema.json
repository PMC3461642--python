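{
  "$defs": {
    "CalibrationConfig": {
      "additionalProperties": false,
      "description": "Anchors for the free degrees of freedom; either may be omitted.",
      "properties": {
        "rv_liters": {
          "anyOf": [
            {
              "exclusiveMinimum": 0,
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Rv Liters"
        },
        "rv_tlc": {
          "anyOf": [
            {
              "exclusiveMinimum": 0,
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Rv Tlc"
        },
        "tolerance": {
          "default": 1e-06,
          "exclusiveMinimum": 0,
          "title": "Tolerance",
          "type": "number"
        }
      },
      "title": "CalibrationConfig",
      "type": "object"
    },
    "ScenarioConfig": {
      "additionalProperties": false,
      "description": "Inline scenario definition (alternative to a preset name).",
      "properties": {
        "height_cm": {
          "exclusiveMinimum": 0,
          "title": "Height Cm",
          "type": "number"
        },
        "k_per_cmh2o": {
          "exclusiveMinimum": 0,
          "title": "K Per Cmh2O",
          "type": "number"
        },
        "n_layers": {
          "default": 350,
          "minimum": 1,
          "title": "N Layers",
          "type": "integer"
        },
        "n_total": {
          "minimum": 0,
          "title": "N Total",
          "type": "number"
        },
        "name": {
          "default": "custom",
          "title": "Name",
          "type": "string"
        },
        "p_rv_apex_cmh2o": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "P Rv Apex Cmh2O"
        },
        "p_tlc_apex_cmh2o": {
          "title": "P Tlc Apex Cmh2O",
          "type": "number"
        },
        "p_tm_cmh2o": {
          "minimum": 0,
          "title": "P Tm Cmh2O",
          "type": "number"
        },
        "rho_frac": {
          "default": 0.25,
          "maximum": 1,
          "minimum": 0,
          "title": "Rho Frac",
          "type": "number"
        },
        "v_max_ul": {
          "exclusiveMinimum": 0,
          "title": "V Max Ul",
          "type": "number"
        },
        "v_min_ul": {
          "minimum": 0,
          "title": "V Min Ul",
          "type": "number"
        }
      },
      "required": [
        "height_cm",
        "n_total",
        "v_max_ul",
        "v_min_ul",
        "k_per_cmh2o",
        "p_tlc_apex_cmh2o",
        "p_tm_cmh2o"
      ],
      "title": "ScenarioConfig",
      "type": "object"
    },
    "SweepConfig": {
      "additionalProperties": false,
      "properties": {
        "dominance": {
          "default": false,
          "title": "Dominance",
          "type": "boolean"
        },
        "mode": {
          "default": "one_at_a_time",
          "enum": [
            "one_at_a_time",
            "joint"
          ],
          "title": "Mode",
          "type": "string"
        },
        "parameters": {
          "default": [
            "n",
            "k",
            "vmin_vmax",
            "p_tm"
          ],
          "items": {
            "type": "string"
          },
          "title": "Parameters",
          "type": "array"
        },
        "points": {
          "default": 3,
          "minimum": 2,
          "title": "Points",
          "type": "integer"
        },
        "span": {
          "default": 0.25,
          "minimum": 0,
          "title": "Span",
          "type": "number"
        }
      },
      "title": "SweepConfig",
      "type": "object"
    },
    "TreatmentBlock": {
      "additionalProperties": false,
      "properties": {
        "llt": {
          "$ref": "#/$defs/TreatmentConfig"
        },
        "ult": {
          "$ref": "#/$defs/TreatmentConfig"
        }
      },
      "required": [
        "ult",
        "llt"
      ],
      "title": "TreatmentBlock",
      "type": "object"
    },
    "TreatmentConfig": {
      "additionalProperties": false,
      "description": "One volume-reduction arm. ``region`` is [z_lo, z_hi) cm from the\napex, or the shorthand \"upper\"/\"lower\" for the apical/basal half.",
      "properties": {
        "height_post_cm": {
          "exclusiveMinimum": 0,
          "title": "Height Post Cm",
          "type": "number"
        },
        "n_removed": {
          "minimum": 0,
          "title": "N Removed",
          "type": "number"
        },
        "p_rv_apex_post_cmh2o": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "P Rv Apex Post Cmh2O"
        },
        "p_tlc_apex_post_cmh2o": {
          "title": "P Tlc Apex Post Cmh2O",
          "type": "number"
        },
        "p_tm_post_cmh2o": {
          "minimum": 0,
          "title": "P Tm Post Cmh2O",
          "type": "number"
        },
        "region": {
          "anyOf": [
            {
              "enum": [
                "upper",
                "lower"
              ],
              "type": "string"
            },
            {
              "maxItems": 2,
              "minItems": 2,
              "prefixItems": [
                {
                  "type": "number"
                },
                {
                  "type": "number"
                }
              ],
              "type": "array"
            }
          ],
          "title": "Region"
        }
      },
      "required": [
        "region",
        "n_removed",
        "p_tlc_apex_post_cmh2o",
        "p_tm_post_cmh2o",
        "height_post_cm"
      ],
      "title": "TreatmentConfig",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "description": "Top-level configuration for every command.",
  "properties": {
    "calibration": {
      "anyOf": [
        {
          "$ref": "#/$defs/CalibrationConfig"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "log_level": {
      "default": "INFO",
      "enum": [
        "DEBUG",
        "INFO",
        "WARNING",
        "ERROR"
      ],
      "title": "Log Level",
      "type": "string"
    },
    "plots": {
      "default": false,
      "title": "Plots",
      "type": "boolean"
    },
    "scenario": {
      "anyOf": [
        {
          "enum": [
            "healthy",
            "emphysema"
          ],
          "type": "string"
        },
        {
          "$ref": "#/$defs/ScenarioConfig"
        }
      ],
      "title": "Scenario"
    },
    "sweep": {
      "anyOf": [
        {
          "$ref": "#/$defs/SweepConfig"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "treatment": {
      "anyOf": [
        {
          "$ref": "#/$defs/TreatmentBlock"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    }
  },
  "required": [
    "scenario"
  ],
  "title": "RunConfig",
  "type": "object"
}
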