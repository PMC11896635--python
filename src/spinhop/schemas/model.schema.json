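{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "spinhop model system",
  "description": "Linear-vibronic-coupling model: harmonic modes, diabatic singlet/triplet surfaces, geometry-dependent SOC. Numeric keys carry explicit unit suffixes.",
  "type": "object",
  "additionalProperties": false,
  "required": ["modes", "electronic"],
  "properties": {
    "label": {"type": "string"},
    "modes": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "additionalProperties": false,
        "required": ["frequency_cm1", "reduced_mass_amu"],
        "properties": {
          "frequency_cm1": {"type": "number", "exclusiveMinimum": 0},
          "reduced_mass_amu": {"type": "number", "exclusiveMinimum": 0},
          "equilibrium": {"type": "number", "default": 0.0},
          "name": {"type": "string"}
        }
      }
    },
    "electronic": {
      "type": "object",
      "additionalProperties": false,
      "required": ["n_singlets", "n_triplets", "vertical_energies_ev"],
      "properties": {
        "n_singlets": {"type": "integer", "minimum": 1},
        "n_triplets": {"type": "integer", "minimum": 0},
        "vertical_energies_ev": {
          "type": "array", "items": {"type": "number"},
          "description": "singlets first (ascending, ground state index 0), then triplets"
        },
        "intrastate_gradients_ev": {
          "type": "array", "items": {"type": "array", "items": {"type": "number"}},
          "description": "kappa, shape (n_states, n_modes), eV per bohr"
        },
        "interstate_couplings_ev": {
          "type": "array",
          "items": {
            "type": "object",
            "additionalProperties": false,
            "required": ["block", "i", "j", "mode", "value_ev"],
            "properties": {
              "block": {"enum": ["singlet", "triplet"]},
              "i": {"type": "integer", "minimum": 0},
              "j": {"type": "integer", "minimum": 0},
              "mode": {"type": "integer", "minimum": 0},
              "value_ev": {"type": "number"}
            }
          }
        },
        "oscillator_strengths": {
          "type": "array", "items": {"type": "number", "minimum": 0},
          "description": "one entry per excited singlet"
        }
      }
    },
    "soc": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "base_soc_cm1": {
          "type": "array",
          "items": {
            "type": "object",
            "additionalProperties": false,
            "required": ["singlet", "triplet", "component"],
            "properties": {
              "singlet": {"type": "integer", "minimum": 0},
              "triplet": {"type": "integer", "minimum": 0},
              "component": {"type": "integer", "minimum": 0, "maximum": 2,
                            "description": "0,1,2 denote M_S = -1, 0, +1"},
              "re_cm1": {"type": "number"},
              "im_cm1": {"type": "number"}
            }
          }
        },
        "modulation": {
          "type": "array",
          "items": {
            "type": "object",
            "additionalProperties": false,
            "required": ["coordinate"],
            "properties": {
              "coordinate": {"type": ["string", "integer"]},
              "linear_cm1": {"type": "number", "default": 0},
              "quadratic_cm1": {"type": "number", "default": 0},
              "entries": {
                "type": "array",
                "items": {"type": "array", "items": {"type": "integer"},
                          "minItems": 3, "maxItems": 3}
              }
            }
          }
        }
      }
    }
  }
}
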