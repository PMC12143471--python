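{
  "$defs": {
    "ConnectivityReport": {
      "properties": {
        "within": {
          "additionalProperties": {
            "type": "number"
          },
          "title": "Within",
          "type": "object"
        },
        "within_pairs": {
          "additionalProperties": {
            "type": "integer"
          },
          "title": "Within Pairs",
          "type": "object"
        },
        "between": {
          "title": "Between",
          "type": "number"
        },
        "between_pairs": {
          "title": "Between Pairs",
          "type": "integer"
        },
        "between_by_community": {
          "additionalProperties": {
            "type": "number"
          },
          "title": "Between By Community",
          "type": "object"
        }
      },
      "required": [
        "within",
        "within_pairs",
        "between",
        "between_pairs",
        "between_by_community"
      ],
      "title": "ConnectivityReport",
      "type": "object"
    },
    "GroupReport": {
      "properties": {
        "label": {
          "title": "Label",
          "type": "string"
        },
        "n_participants": {
          "title": "N Participants",
          "type": "integer"
        },
        "edges": {
          "additionalProperties": {
            "type": "number"
          },
          "title": "Edges",
          "type": "object"
        },
        "partition": {
          "$ref": "#/$defs/PartitionReport"
        },
        "connectivity": {
          "$ref": "#/$defs/ConnectivityReport"
        },
        "centrality": {
          "additionalProperties": {
            "additionalProperties": {
              "type": "number"
            },
            "type": "object"
          },
          "title": "Centrality",
          "type": "object"
        },
        "cronbach_alpha": {
          "additionalProperties": {
            "type": "number"
          },
          "title": "Cronbach Alpha",
          "type": "object"
        },
        "top_strength_node": {
          "title": "Top Strength Node",
          "type": "string"
        },
        "top_bridge_node": {
          "title": "Top Bridge Node",
          "type": "string"
        },
        "anxiety_community": {
          "title": "Anxiety Community",
          "type": "integer"
        },
        "depression_community": {
          "title": "Depression Community",
          "type": "integer"
        }
      },
      "required": [
        "label",
        "n_participants",
        "edges",
        "partition",
        "connectivity",
        "centrality",
        "cronbach_alpha",
        "top_strength_node",
        "top_bridge_node",
        "anxiety_community",
        "depression_community"
      ],
      "title": "GroupReport",
      "type": "object"
    },
    "PartitionReport": {
      "properties": {
        "method": {
          "title": "Method",
          "type": "string"
        },
        "n_communities": {
          "title": "N Communities",
          "type": "integer"
        },
        "modularity_q": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "title": "Modularity Q"
        },
        "assignment": {
          "additionalProperties": {
            "type": "integer"
          },
          "title": "Assignment",
          "type": "object"
        }
      },
      "required": [
        "method",
        "n_communities",
        "modularity_q",
        "assignment"
      ],
      "title": "PartitionReport",
      "type": "object"
    },
    "PermutationReport": {
      "properties": {
        "statistic": {
          "title": "Statistic",
          "type": "string"
        },
        "contrast": {
          "title": "Contrast",
          "type": "string"
        },
        "observed_diff": {
          "title": "Observed Diff",
          "type": "number"
        },
        "observed_values": {
          "items": {
            "type": "number"
          },
          "title": "Observed Values",
          "type": "array"
        },
        "p_value": {
          "title": "P Value",
          "type": "number"
        },
        "n_iter": {
          "title": "N Iter",
          "type": "integer"
        },
        "seed": {
          "title": "Seed",
          "type": "integer"
        }
      },
      "required": [
        "statistic",
        "contrast",
        "observed_diff",
        "observed_values",
        "p_value",
        "n_iter",
        "seed"
      ],
      "title": "PermutationReport",
      "type": "object"
    },
    "Provenance": {
      "properties": {
        "config_hash": {
          "title": "Config Hash",
          "type": "string"
        },
        "package_version": {
          "title": "Package Version",
          "type": "string"
        },
        "seeds": {
          "additionalProperties": {
            "type": "integer"
          },
          "title": "Seeds",
          "type": "object"
        },
        "n_rows_input": {
          "title": "N Rows Input",
          "type": "integer"
        },
        "n_rows_included": {
          "title": "N Rows Included",
          "type": "integer"
        },
        "generated_at": {
          "title": "Generated At",
          "type": "string"
        }
      },
      "required": [
        "config_hash",
        "package_version",
        "seeds",
        "n_rows_input",
        "n_rows_included",
        "generated_at"
      ],
      "title": "Provenance",
      "type": "object"
    },
    "RankCorrelationReport": {
      "properties": {
        "field": {
          "title": "Field",
          "type": "string"
        },
        "rho": {
          "title": "Rho",
          "type": "number"
        },
        "p_value": {
          "title": "P Value",
          "type": "number"
        }
      },
      "required": [
        "field",
        "rho",
        "p_value"
      ],
      "title": "RankCorrelationReport",
      "type": "object"
    }
  },
  "properties": {
    "groups": {
      "additionalProperties": {
        "$ref": "#/$defs/GroupReport"
      },
      "title": "Groups",
      "type": "object"
    },
    "permutation_tests": {
      "items": {
        "$ref": "#/$defs/PermutationReport"
      },
      "title": "Permutation Tests",
      "type": "array"
    },
    "rank_correlations": {
      "items": {
        "$ref": "#/$defs/RankCorrelationReport"
      },
      "title": "Rank Correlations",
      "type": "array"
    },
    "group_characteristics": {
      "items": {
        "additionalProperties": true,
        "type": "object"
      },
      "title": "Group Characteristics",
      "type": "array"
    },
    "item_comparisons": {
      "items": {
        "additionalProperties": true,
        "type": "object"
      },
      "title": "Item Comparisons",
      "type": "array"
    },
    "partition_agreement_between_groups": {
      "title": "Partition Agreement Between Groups",
      "type": "number"
    },
    "provenance": {
      "$ref": "#/$defs/Provenance"
    }
  },
  "required": [
    "groups",
    "permutation_tests",
    "rank_correlations",
    "group_characteristics",
    "item_comparisons",
    "partition_agreement_between_groups",
    "provenance"
  ],
  "title": "StudyReport",
  "type": "object"
}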