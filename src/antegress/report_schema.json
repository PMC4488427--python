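{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "antegress analysis report",
  "type": "object",
  "required": [
    "schema_version",
    "provenance",
    "per_width",
    "beta_trend",
    "interval_tests",
    "correlations",
    "escaped_count_tests",
    "group_summary",
    "notes"
  ],
  "properties": {
    "schema_version": {"type": "string"},
    "provenance": {
      "type": "object",
      "required": ["package_version", "source", "bin_rule", "config_hash", "timestamp"],
      "properties": {
        "package_version": {"type": "string"},
        "source": {"type": "string"},
        "seed": {"type": ["integer", "null"]},
        "bin_rule": {"type": "string"},
        "ttest_variant": {"type": "string"},
        "config_hash": {"type": "string"},
        "timestamp": {"type": "string"}
      }
    },
    "per_width": {
      "type": "array",
      "items": {
        "type": "object",
        "required": [
          "width_cm", "n_trials", "n_intervals", "mean_interval_s", "Q",
          "alpha", "beta", "epsilon", "sse", "converged",
          "threshold_s", "min_size", "n_groups", "mean_QS"
        ],
        "properties": {
          "width_cm": {"type": "number"},
          "n_trials": {"type": "integer"},
          "n_intervals": {"type": "integer"},
          "mean_interval_s": {"type": ["number", "null"]},
          "Q": {"type": ["number", "null"]},
          "alpha": {"type": ["number", "null"]},
          "beta": {"type": ["number", "null"]},
          "epsilon": {"type": ["number", "null"]},
          "sse": {"type": ["number", "null"]},
          "converged": {"type": "boolean"},
          "threshold_s": {"type": ["number", "null"]},
          "min_size": {"type": "integer"},
          "n_groups": {"type": "integer"},
          "mean_QS": {"type": ["number", "null"]}
        }
      }
    },
    "beta_trend": {
      "type": ["object", "null"],
      "required": ["slope", "intercept", "r_squared"],
      "properties": {
        "slope": {"type": "number"},
        "intercept": {"type": "number"},
        "r_squared": {"type": "number"}
      }
    },
    "interval_tests": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["width_a", "width_b", "statistic", "p", "stars"],
        "properties": {
          "width_a": {"type": "number"},
          "width_b": {"type": "number"},
          "statistic": {"type": "number"},
          "p": {"type": "number"},
          "stars": {"type": "integer"},
          "n_a": {"type": "integer"},
          "n_b": {"type": "integer"}
        }
      }
    },
    "correlations": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["width_cm", "r", "p", "n"],
        "properties": {
          "width_cm": {"type": "number"},
          "r": {"type": "number"},
          "p": {"type": "number"},
          "n": {"type": "integer"}
        }
      }
    },
    "escaped_count_tests": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["width_cm", "statistic", "p", "stars", "n_repellent", "n_control"],
        "properties": {
          "width_cm": {"type": "number"},
          "statistic": {"type": "number"},
          "p": {"type": "number"},
          "stars": {"type": "integer"},
          "n_repellent": {"type": "integer"},
          "n_control": {"type": "integer"}
        }
      }
    },
    "group_summary": {
      "type": "object",
      "required": ["n_groups_total", "n_singular_excluded"],
      "properties": {
        "n_groups_total": {"type": "integer"},
        "n_singular_excluded": {"type": "integer"}
      }
    },
    "notes": {"type": "array", "items": {"type": "string"}}
  }
}
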