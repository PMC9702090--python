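{
  "type": "object",
  "required": ["seed", "stages", "mega_environments", "traits", "varcomp", "selection"],
  "properties": {
    "seed": {"type": "integer"},
    "stages": {"type": "array", "items": {"type": "string"}},
    "mega_environments": {
      "type": "object",
      "additionalProperties": {"type": "array", "items": {"type": "string"}}
    },
    "delineation_ari_vs_archetypes": {"type": "number"},
    "traits": {"type": "array", "items": {"type": "string"}},
    "varcomp": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["variances", "sigma2_P", "H2", "Ac", "converged"],
        "properties": {
          "variances": {"type": "object", "additionalProperties": {"type": "number"}},
          "sigma2_P": {"type": "number"},
          "H2": {"type": "number"},
          "Ac": {"type": "number"},
          "converged": {"type": "boolean"},
          "lrt_pvalues": {"type": "object"}
        }
      }
    },
    "selection": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["selected", "n_factors", "explained_variance_pct"],
        "properties": {
          "selected": {"type": "array", "items": {"type": "string"}},
          "n_factors": {"type": "integer"},
          "explained_variance_pct": {"type": "number"},
          "dS_pct_mean": {"type": "object", "additionalProperties": {"type": "number"}},
          "dS_pct_stability": {"type": "object", "additionalProperties": {"type": "number"}}
        }
      }
    },
    "cross_me_counts": {
      "type": "object",
      "additionalProperties": {"type": "integer"}
    }
  }
}
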