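{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "orthillusion analysis report",
  "type": "object",
  "required": ["provenance", "timestamps", "skipped_stages", "design_check", "control_reference"],
  "properties": {
    "provenance": {
      "type": "object",
      "required": ["package_version", "config", "seed"],
      "properties": {
        "package_version": {"type": "string"},
        "config": {"type": "object"},
        "seed": {"type": "integer"},
        "n_trials": {"type": "integer"}
      }
    },
    "timestamps": {"type": "object"},
    "skipped_stages": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["stage", "reason"]
      }
    },
    "design_check": {
      "type": "object",
      "required": ["expected_per_cell", "n_flagged_cells"]
    },
    "control_reference": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["mean_offset_deg", "sd_offset_deg", "threshold_deg", "multiplier", "n_control", "centering_mode"]
      }
    },
    "error_counts": {"type": "object"},
    "bootstrap": {"type": "object"},
    "shuffle_test": {
      "type": "object",
      "required": ["observed_statistic", "n_shuffles", "p_value"]
    },
    "cdf_test": {"type": "object"},
    "elapsed_s": {"type": "number"}
  }
}
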