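{
  "$defs": {
    "StateResult": {
      "additionalProperties": false,
      "description": "Avalanche statistics of one state (up or down).",
      "properties": {
        "state": {
          "title": "State",
          "type": "string"
        },
        "family": {
          "title": "Family",
          "type": "string"
        },
        "n_avalanches": {
          "additionalProperties": {
            "type": "integer"
          },
          "title": "N Avalanches",
          "type": "object"
        },
        "tau": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Tau"
        },
        "tau_unc": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Tau Unc"
        },
        "alpha": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Alpha"
        },
        "alpha_unc": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Alpha Unc"
        },
        "beta_S": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Beta S"
        },
        "beta_S_unc": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Beta S Unc"
        },
        "beta_T": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Beta T"
        },
        "beta_T_unc": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Beta T Unc"
        },
        "gamma": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Gamma"
        },
        "gamma_unc": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Gamma Unc"
        },
        "size_fit": {
          "anyOf": [
            {
              "additionalProperties": true,
              "type": "object"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Size Fit"
        },
        "duration_fit": {
          "anyOf": [
            {
              "additionalProperties": true,
              "type": "object"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Duration Fit"
        },
        "scaling_relation": {
          "anyOf": [
            {
              "additionalProperties": true,
              "type": "object"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Scaling Relation"
        },
        "beta_relation": {
          "anyOf": [
            {
              "additionalProperties": true,
              "type": "object"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Beta Relation"
        }
      },
      "required": [
        "state",
        "family",
        "n_avalanches"
      ],
      "title": "StateResult",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "description": "Full per-recording analysis output.",
  "properties": {
    "label": {
      "title": "Label",
      "type": "string"
    },
    "seed": {
      "title": "Seed",
      "type": "integer"
    },
    "n_neurons": {
      "title": "N Neurons",
      "type": "integer"
    },
    "duration_s": {
      "title": "Duration S",
      "type": "number"
    },
    "frame_interval_s": {
      "title": "Frame Interval S",
      "type": "number"
    },
    "state_durations": {
      "additionalProperties": true,
      "title": "State Durations",
      "type": "object"
    },
    "isi": {
      "additionalProperties": true,
      "title": "Isi",
      "type": "object"
    },
    "up": {
      "$ref": "#/$defs/StateResult"
    },
    "down": {
      "$ref": "#/$defs/StateResult"
    }
  },
  "required": [
    "label",
    "seed",
    "n_neurons",
    "duration_s",
    "frame_interval_s",
    "state_durations",
    "isi",
    "up",
    "down"
  ],
  "title": "RecordingReport",
  "type": "object"
}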