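{
  "type": "object",
  "required": ["config", "seed", "stage_seeds", "priors_used", "ratio", "unit_note"],
  "properties": {
    "seed": {"type": "integer"},
    "config": {"type": "object", "required": ["mode", "seed"]},
    "stage_seeds": {
      "type": "object",
      "required": ["data", "theta_seq", "theta_msat", "ratio"]
    },
    "diversity": {"type": ["object", "null"]},
    "theta_seq": {
      "type": ["object", "null"],
      "required": ["mean", "mode", "ci95", "ess", "prior_bounds", "converged", "flags"],
      "properties": {
        "mean": {"type": "number"},
        "mode": {"type": "number"},
        "ci95": {"type": "array", "items": {"type": "number"}},
        "ess": {"type": "number"},
        "converged": {"type": "boolean"}
      }
    },
    "theta_msat": {
      "type": ["object", "null"],
      "required": ["mean", "mode", "ci95", "ess", "prior_bounds", "converged", "flags"]
    },
    "priors_used": {
      "type": "object",
      "required": ["theta_n", "theta_m", "mu_n", "mu_m", "generation_time", "source", "rounded"],
      "properties": {
        "theta_n": {"type": "array", "items": {"type": "number"}},
        "theta_m": {"type": "array", "items": {"type": "number"}},
        "mu_n": {"type": "array", "items": {"type": "number"}},
        "mu_m": {"type": "array", "items": {"type": "number"}},
        "generation_time": {"type": "number"},
        "source": {"type": "string"},
        "rounded": {"type": "boolean"}
      }
    },
    "ratio": {
      "type": "object",
      "required": [
        "mean", "sd", "ci95", "reduction_mean_pct", "reduction_range_pct",
        "ne_mean", "nef_mean", "mode", "n_samples", "seed"
      ],
      "properties": {
        "mean": {"type": "number"},
        "sd": {"type": "number"},
        "ci95": {"type": "array", "items": {"type": "number"}},
        "reduction_mean_pct": {"type": "integer"},
        "reduction_range_pct": {"type": "array", "items": {"type": "integer"}},
        "mode": {"type": "string"},
        "n_samples": {"type": "integer"},
        "seed": {"type": "integer"}
      }
    },
    "unit_note": {"type": "string"}
  }
}
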