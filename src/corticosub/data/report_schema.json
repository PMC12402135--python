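{
  "type": "object",
  "required": ["seed", "parameters", "stages", "mode"],
  "properties": {
    "seed": {"type": "number"},
    "mode": {"type": "string"},
    "parameters": {"type": "object"},
    "stages": {
      "type": "object",
      "properties": {
        "fc": {
          "type": "object",
          "required": ["n_subjects", "dof", "n_edges", "alpha", "n_comparisons"]
        },
        "communities": {
          "type": "object",
          "required": ["gamma", "n_communities", "q_value", "partition"]
        },
        "validation": {
          "type": "object",
          "required": ["q_real", "cpl_real", "tests"]
        },
        "hubs": {
          "type": "object",
          "required": ["types", "percentages"]
        },
        "convergence": {
          "type": "object",
          "required": ["counts"]
        },
        "attack": {
          "type": "object",
          "required": ["le_target", "nulls"]
        }
      }
    }
  }
}
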