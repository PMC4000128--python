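{
 "$defs": {
  "CalibrationSpec": {
   "additionalProperties": false,
   "description": "Ordered risk-group labels with population proportions (low -> high risk).",
   "properties": {
    "labels": {
     "items": {
      "type": "string"
     },
     "title": "Labels",
     "type": "array"
    },
    "proportions": {
     "items": {
      "type": "number"
     },
     "title": "Proportions",
     "type": "array"
    }
   },
   "required": [
    "labels",
    "proportions"
   ],
   "title": "CalibrationSpec",
   "type": "object"
  },
  "GeneEntry": {
   "additionalProperties": false,
   "description": "One gene's role in a signature.",
   "properties": {
    "gene_id": {
     "title": "Gene Id",
     "type": "string"
    },
    "weight": {
     "default": 1.0,
     "title": "Weight",
     "type": "number"
    },
    "group": {
     "anyOf": [
      {
       "type": "string"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Group"
    },
    "stratum": {
     "anyOf": [
      {
       "type": "string"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Stratum"
    },
    "is_reference": {
     "default": false,
     "title": "Is Reference",
     "type": "boolean"
    }
   },
   "required": [
    "gene_id"
   ],
   "title": "GeneEntry",
   "type": "object"
  },
  "GroupSpec": {
   "additionalProperties": false,
   "description": "Aggregation parameters for one gene group of a grouped_threshold scorer.",
   "properties": {
    "weight": {
     "default": 1.0,
     "title": "Weight",
     "type": "number"
    },
    "clip_low": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Clip Low"
    },
    "clip_high": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Clip High"
    }
   },
   "title": "GroupSpec",
   "type": "object"
  }
 },
 "additionalProperties": false,
 "description": "A complete, validated description of one prognostic signature.",
 "properties": {
  "name": {
   "title": "Name",
   "type": "string"
  },
  "archetype": {
   "enum": [
    "centroid_subtype",
    "centroid_risk",
    "weighted_sum",
    "difference_of_means",
    "grouped_threshold"
   ],
   "title": "Archetype",
   "type": "string"
  },
  "genes": {
   "items": {
    "$ref": "#/$defs/GeneEntry"
   },
   "title": "Genes",
   "type": "array"
  },
  "class_order": {
   "items": {
    "type": "string"
   },
   "title": "Class Order",
   "type": "array"
  },
  "centroids": {
   "additionalProperties": {
    "additionalProperties": {
     "type": "number"
    },
    "type": "object"
   },
   "title": "Centroids",
   "type": "object"
  },
  "ror_coefficients": {
   "additionalProperties": {
    "type": "number"
   },
   "title": "Ror Coefficients",
   "type": "object"
  },
  "reference_class": {
   "anyOf": [
    {
     "type": "string"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Reference Class"
  },
  "groups": {
   "additionalProperties": {
    "$ref": "#/$defs/GroupSpec"
   },
   "title": "Groups",
   "type": "object"
  },
  "intercept": {
   "default": 0.0,
   "title": "Intercept",
   "type": "number"
  },
  "risk_direction": {
   "default": 1,
   "enum": [
    1,
    -1
   ],
   "title": "Risk Direction",
   "type": "integer"
  },
  "subtype_correlation": {
   "default": "spearman",
   "enum": [
    "spearman",
    "pearson"
   ],
   "title": "Subtype Correlation",
   "type": "string"
  },
  "ror_correlation": {
   "default": "pearson",
   "enum": [
    "pearson",
    "spearman"
   ],
   "title": "Ror Correlation",
   "type": "string"
  },
  "calibration": {
   "additionalProperties": {
    "$ref": "#/$defs/CalibrationSpec"
   },
   "title": "Calibration",
   "type": "object"
  },
  "provenance": {
   "anyOf": [
    {
     "type": "string"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Provenance"
  }
 },
 "required": [
  "name",
  "archetype"
 ],
 "title": "progsig signature definition",
 "type": "object",
 "$schema": "https://json-schema.org/draft/2020-12/schema"
}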