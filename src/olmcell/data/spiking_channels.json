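{
  "schema_version": 1,
  "comment": "Stylized HH-type kinetics for the non-sodium spiking channels authored for this package (synthetic; kca is a voltage-gated surrogate without calcium dynamics). Voltages in mV, time constants in ms, reversals in mV.",
  "channels": {
    "kdrf": {
      "family": "k",
      "erev": -85.0,
      "gates": {
        "n": {
          "exponent": 4,
          "inf": {
            "kind": "boltzmann",
            "vhalf": -12.0,
            "q": -9.0
          },
          "tau": {
            "kind": "sumsigmoid",
            "base": 0.8,
            "amp": 4.0,
            "vhalf": -40.0,
            "q": 15.0
          }
        }
      }
    },
    "kdrs": {
      "family": "k",
      "erev": -85.0,
      "gates": {
        "n": {
          "exponent": 2,
          "inf": {
            "kind": "boltzmann",
            "vhalf": -25.0,
            "q": -9.0
          },
          "tau": {
            "kind": "sumsigmoid",
            "base": 20.0,
            "amp": 130.0,
            "vhalf": -45.0,
            "q": 10.0
          }
        }
      }
    },
    "ka": {
      "family": "k",
      "erev": -85.0,
      "gates": {
        "a": {
          "exponent": 1,
          "inf": {
            "kind": "boltzmann",
            "vhalf": -47.0,
            "q": -3.5
          },
          "tau": {
            "kind": "constant",
            "value": 2.0
          }
        },
        "b": {
          "exponent": 1,
          "inf": {
            "kind": "sumsigmoid",
            "base": 0.3,
            "amp": 0.7,
            "vhalf": -70.0,
            "q": 6.0
          },
          "tau": {
            "kind": "sumsigmoid",
            "base": 25.0,
            "amp": 100.0,
            "vhalf": -70.0,
            "q": 8.0
          }
        }
      }
    },
    "m": {
      "family": "k",
      "erev": -85.0,
      "gates": {
        "m": {
          "exponent": 1,
          "inf": {
            "kind": "boltzmann",
            "vhalf": -30.0,
            "q": -6.0
          },
          "tau": {
            "kind": "sumsigmoid",
            "base": 40.0,
            "amp": 180.0,
            "vhalf": -45.0,
            "q": 10.0
          }
        }
      }
    },
    "cat": {
      "family": "ca",
      "erev": 120.0,
      "gates": {
        "m": {
          "exponent": 2,
          "inf": {
            "kind": "boltzmann",
            "vhalf": -50.0,
            "q": -6.5
          },
          "tau": {
            "kind": "sumsigmoid",
            "base": 3.0,
            "amp": 20.0,
            "vhalf": -70.0,
            "q": 8.0
          }
        },
        "h": {
          "exponent": 1,
          "inf": {
            "kind": "boltzmann",
            "vhalf": -75.0,
            "q": 6.0
          },
          "tau": {
            "kind": "constant",
            "value": 60.0
          }
        }
      }
    },
    "cal": {
      "family": "ca",
      "erev": 120.0,
      "gates": {
        "m": {
          "exponent": 2,
          "inf": {
            "kind": "boltzmann",
            "vhalf": -20.0,
            "q": -7.0
          },
          "tau": {
            "kind": "constant",
            "value": 2.5
          }
        }
      }
    },
    "kca": {
      "family": "k",
      "erev": -85.0,
      "gates": {
        "z": {
          "exponent": 1,
          "inf": {
            "kind": "boltzmann",
            "vhalf": -25.0,
            "q": -6.0
          },
          "tau": {
            "kind": "constant",
            "value": 40.0
          }
        }
      }
    }
  }
}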