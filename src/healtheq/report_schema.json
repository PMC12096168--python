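{
  "title": "healtheq pipeline report",
  "description": "Machine-checkable schema of report.json written by run_pipeline; types use Python names. Required keys must be present; others are optional.",
  "type": "object",
  "required": [
    "seed", "config", "n", "cleaning", "outcome_rate", "chi2_screen",
    "screen_kept", "importance_ranking", "oob_store", "lambda_min",
    "lambda_1se", "selected_factors", "logit", "concentration_index",
    "outcome_mean", "direction", "residual_term",
    "decomposition_identity_gap"
  ],
  "properties": {
    "seed": {"type": "int"},
    "config": {"type": "dict"},
    "n": {"type": "int"},
    "cleaning": {"type": "dict"},
    "outcome_rate": {"type": "float"},
    "chi2_screen": {"type": "dict"},
    "screen_kept": {"type": "list"},
    "importance_ranking": {"type": "list"},
    "oob_store": {"type": "dict"},
    "lambda_min": {"type": "float"},
    "lambda_1se": {"type": "float"},
    "selected_factors": {"type": "list"},
    "logit": {"type": "dict"},
    "concentration_index": {"type": "float"},
    "outcome_mean": {"type": "float"},
    "direction": {"type": "str"},
    "residual_term": {"type": "float"},
    "decomposition_identity_gap": {"type": "float"},
    "generator_beta0": {"type": "float"},
    "search_best_score": {"type": "float"}
  },
  "additionalProperties": false
}
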