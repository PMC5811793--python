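{
 "$defs": {
  "AnalyzeConfig": {
   "additionalProperties": false,
   "properties": {
    "Delta_short_ms": {
     "default": 70.0,
     "title": "Delta Short Ms",
     "type": "number"
    },
    "Delta_long_ms": {
     "default": 400.0,
     "title": "Delta Long Ms",
     "type": "number"
    },
    "denominator": {
     "default": "fixed_b0",
     "enum": [
      "fixed_b0",
      "fixed_q0"
     ],
     "title": "Denominator",
     "type": "string"
    }
   },
   "title": "AnalyzeConfig",
   "type": "object"
  },
  "ContoursConfig": {
   "additionalProperties": false,
   "properties": {
    "b_grid": {
     "default": [
      0.5,
      1.0,
      1.5,
      2.0,
      2.5,
      3.0,
      3.5,
      4.0
     ],
     "items": {
      "type": "number"
     },
     "title": "B Grid",
     "type": "array"
    },
    "Delta_grid_ms": {
     "default": [
      70,
      100,
      150,
      200,
      250,
      300,
      350,
      400
     ],
     "items": {
      "type": "number"
     },
     "title": "Delta Grid Ms",
     "type": "array"
    },
    "b0_fraction": {
     "default": 0.2,
     "title": "B0 Fraction",
     "type": "number"
    }
   },
   "title": "ContoursConfig",
   "type": "object"
  },
  "CurvesConfig": {
   "additionalProperties": false,
   "properties": {
    "b0_fractions": {
     "default": [
      0.0,
      0.1,
      0.2,
      0.3
     ],
     "items": {
      "type": "number"
     },
     "title": "B0 Fractions",
     "type": "array"
    },
    "direction": {
     "anyOf": [
      {
       "items": {
        "type": "number"
       },
       "type": "array"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Direction"
    }
   },
   "title": "CurvesConfig",
   "type": "object"
  },
  "ProtocolConfig": {
   "additionalProperties": false,
   "description": "Acquisition protocol; defaults reproduce the postmortem experiment.",
   "properties": {
    "Delta_list_ms": {
     "default": [
      70,
      100,
      150,
      200,
      250,
      300,
      350,
      400
     ],
     "items": {
      "type": "number"
     },
     "title": "Delta List Ms",
     "type": "array"
    },
    "delta_ms": {
     "default": 2.22,
     "title": "Delta Ms",
     "type": "number"
    },
    "nominal_b": {
     "default": 3.5,
     "title": "Nominal B",
     "type": "number"
    },
    "te_ms": {
     "default": 16.0,
     "title": "Te Ms",
     "type": "number"
    },
    "n_directions": {
     "default": 30,
     "title": "N Directions",
     "type": "integer"
    },
    "reference_mode": {
     "default": "fixed_b0",
     "enum": [
      "fixed_b0",
      "fixed_q0"
     ],
     "title": "Reference Mode",
     "type": "string"
    },
    "b0_at_delta_max": {
     "default": 0.631,
     "title": "B0 At Delta Max",
     "type": "number"
    },
    "n_axes": {
     "default": 3,
     "title": "N Axes",
     "type": "integer"
    },
    "scheme_variant": {
     "default": "modified",
     "enum": [
      "conventional",
      "modified"
     ],
     "title": "Scheme Variant",
     "type": "string"
    }
   },
   "title": "ProtocolConfig",
   "type": "object"
  },
  "SeqcheckConfig": {
   "additionalProperties": false,
   "properties": {
    "q_crusher": {
     "default": 0.046,
     "title": "Q Crusher",
     "type": "number"
    },
    "q_slice": {
     "default": 0.046,
     "title": "Q Slice",
     "type": "number"
    },
    "b_diffusion": {
     "default": [
      3.5,
      0.7,
      0.0
     ],
     "items": {
      "type": "number"
     },
     "title": "B Diffusion",
     "type": "array"
    }
   },
   "title": "SeqcheckConfig",
   "type": "object"
  },
  "ValidateConfig": {
   "additionalProperties": false,
   "properties": {
    "n_walkers": {
     "default": 100000,
     "title": "N Walkers",
     "type": "integer"
    },
    "q_values": {
     "default": [
      0.02,
      0.05,
      0.1
     ],
     "items": {
      "type": "number"
     },
     "title": "Q Values",
     "type": "array"
    },
    "Delta_values_ms": {
     "default": [
      10,
      50,
      200,
      500
     ],
     "items": {
      "type": "number"
     },
     "title": "Delta Values Ms",
     "type": "array"
    },
    "r_um": {
     "default": 5.0,
     "title": "R Um",
     "type": "number"
    },
    "D": {
     "default": 2.0,
     "title": "D",
     "type": "number"
    }
   },
   "title": "ValidateConfig",
   "type": "object"
  }
 },
 "additionalProperties": false,
 "properties": {
  "seed": {
   "default": 0,
   "title": "Seed",
   "type": "integer"
  },
  "log_level": {
   "default": "INFO",
   "title": "Log Level",
   "type": "string"
  },
  "protocol": {
   "$ref": "#/$defs/ProtocolConfig"
  },
  "model": {
   "additionalProperties": true,
   "title": "Model",
   "type": "object"
  },
  "phantom": {
   "additionalProperties": true,
   "title": "Phantom",
   "type": "object"
  },
  "curves": {
   "$ref": "#/$defs/CurvesConfig"
  },
  "contours": {
   "$ref": "#/$defs/ContoursConfig"
  },
  "seqcheck": {
   "$ref": "#/$defs/SeqcheckConfig"
  },
  "validate_mc": {
   "$ref": "#/$defs/ValidateConfig"
  },
  "analyze": {
   "$ref": "#/$defs/AnalyzeConfig"
  }
 },
 "title": "RunConfig",
 "type": "object"
}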