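{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "spinhop run configuration",
  "description": "Pipeline configuration; defaults follow the reference protocol (0.5 fs step, 20 substeps, 200 fs horizon, 298 K, alphas 2/3.5/5, 20 trajectories started in S1).",
  "type": "object",
  "additionalProperties": false,
  "required": ["model_path"],
  "properties": {
    "model_path": {"type": "string"},
    "dt_fs": {"type": "number", "exclusiveMinimum": 0, "default": 0.5},
    "n_substeps": {"type": "integer", "minimum": 1, "default": 20},
    "t_max_fs": {"type": "number", "exclusiveMinimum": 0, "default": 200.0},
    "t_max_per_alpha": {
      "type": "object",
      "additionalProperties": {"type": "number", "exclusiveMinimum": 0}
    },
    "temperature_k": {"type": "number", "minimum": 0, "default": 298.0},
    "n_trajectories": {"type": "integer", "minimum": 1, "default": 20},
    "alphas": {"type": "array", "items": {"type": "number", "minimum": 0},
               "default": [2.0, 3.5, 5.0]},
    "initial_state": {"type": "string", "default": "S1"},
    "seed": {"type": "integer", "default": 1},
    "output_dir": {"type": "string", "default": "spinhop_out"}
  }
}
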