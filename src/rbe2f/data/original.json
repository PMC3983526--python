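{
  "name": "original",
  "provenance": "original",
  "description": "Published kinetic constants of the Rb-E2F switch model (Yao 2008 values).",
  "parameters": {
    "dMC": 0.70,
    "dE": 0.25,
    "dCD": 1.5,
    "dCE": 1.5,
    "dR": 0.06,
    "dRE": 0.03,
    "dRP": 0.06,
    "kP1": 18,
    "kP2": 18,
    "kDP": 3.6,
    "kRE": 180,
    "kkE": 0.4,
    "kkM": 1,
    "kkCD": 0.03,
    "kkCE": 0.35,
    "kCDS": 0.45,
    "kR": 0.18,
    "kb": 0.003,
    "KM": 0.15,
    "KCD": 0.92,
    "KRP": 0.01,
    "KS": 0.50,
    "KE": 0.15,
    "KCE": 0.92
  }
}
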