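{
  "$defs": {
    "ProfileModel": {
      "properties": {
        "target_type": {
          "title": "Target Type",
          "type": "string"
        },
        "bin_edges_um": {
          "items": {
            "type": "number"
          },
          "title": "Bin Edges Um",
          "type": "array"
        },
        "counts": {
          "items": {
            "type": "integer"
          },
          "title": "Counts",
          "type": "array"
        },
        "density_per_100um2": {
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
          "title": "Density Per 100Um2"
        },
        "n_within_outer": {
          "title": "N Within Outer",
          "type": "integer"
        }
      },
      "required": [
        "target_type",
        "bin_edges_um",
        "counts",
        "n_within_outer"
      ],
      "title": "ProfileModel",
      "type": "object"
    },
    "ProvenanceModel": {
      "properties": {
        "version": {
          "title": "Version",
          "type": "string"
        },
        "seed": {
          "title": "Seed",
          "type": "integer"
        },
        "mode": {
          "title": "Mode",
          "type": "string"
        },
        "config": {
          "additionalProperties": true,
          "title": "Config",
          "type": "object"
        }
      },
      "required": [
        "version",
        "seed",
        "mode",
        "config"
      ],
      "title": "ProvenanceModel",
      "type": "object"
    },
    "RatioModel": {
      "properties": {
        "caf_per_oscc": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Caf Per Oscc"
        },
        "caf_per_oscc_exact": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Caf Per Oscc Exact"
        },
        "caf_per_osteoclast": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Caf Per Osteoclast"
        },
        "caf_per_osteoclast_exact": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Caf Per Osteoclast Exact"
        }
      },
      "title": "RatioModel",
      "type": "object"
    },
    "RoiModel": {
      "properties": {
        "n_surface": {
          "title": "N Surface",
          "type": "integer"
        },
        "n_deep": {
          "title": "N Deep",
          "type": "integer"
        },
        "side": {
          "title": "Side",
          "type": "number"
        },
        "pooled_counts_surface": {
          "additionalProperties": {
            "type": "integer"
          },
          "title": "Pooled Counts Surface",
          "type": "object"
        },
        "pooled_counts_deep": {
          "additionalProperties": {
            "type": "integer"
          },
          "title": "Pooled Counts Deep",
          "type": "object"
        },
        "ratios": {
          "$ref": "#/$defs/RatioModel"
        }
      },
      "required": [
        "n_surface",
        "n_deep",
        "side",
        "pooled_counts_surface",
        "pooled_counts_deep",
        "ratios"
      ],
      "title": "RoiModel",
      "type": "object"
    },
    "SummaryModel": {
      "properties": {
        "target_type": {
          "title": "Target Type",
          "type": "string"
        },
        "fraction_within": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Fraction Within"
        },
        "inner_um": {
          "title": "Inner Um",
          "type": "number"
        },
        "outer_um": {
          "title": "Outer Um",
          "type": "number"
        },
        "n_within_inner": {
          "title": "N Within Inner",
          "type": "integer"
        },
        "n_within_outer": {
          "title": "N Within Outer",
          "type": "integer"
        },
        "defined": {
          "title": "Defined",
          "type": "boolean"
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
        }
      },
      "required": [
        "target_type",
        "inner_um",
        "outer_um",
        "n_within_inner",
        "n_within_outer",
        "defined"
      ],
      "title": "SummaryModel",
      "type": "object"
    }
  },
  "properties": {
    "provenance": {
      "$ref": "#/$defs/ProvenanceModel"
    },
    "cell_counts": {
      "additionalProperties": {
        "type": "integer"
      },
      "title": "Cell Counts",
      "type": "object"
    },
    "roi": {
      "$ref": "#/$defs/RoiModel"
    },
    "profiles": {
      "items": {
        "$ref": "#/$defs/ProfileModel"
      },
      "title": "Profiles",
      "type": "array"
    },
    "summaries": {
      "items": {
        "$ref": "#/$defs/SummaryModel"
      },
      "title": "Summaries",
      "type": "array"
    },
    "strata": {
      "anyOf": [
        {
          "items": {
            "$ref": "#/$defs/SummaryModel"
          },
          "type": "array"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Strata"
    }
  },
  "required": [
    "provenance",
    "cell_counts",
    "roi",
    "profiles",
    "summaries"
  ],
  "title": "PipelineReport",
  "type": "object"
}
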