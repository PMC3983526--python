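{
  "name": "opt2",
  "provenance": "opt2",
  "description": "Second optimization round: 10 free parameters (first-round set minus KCE, kkCD, kRE, KS; plus the Rb phosphorylation rates kP1, kP2) re-fitted, the remainder held at their original values.",
  "parameters": {
    "dMC": 0.70,
    "dE": 0.25,
    "dCD": 1.5,
    "dCE": 1.5,
    "dR": 0.06,
    "dRE": 0.03,
    "dRP": 0.0038691,
    "kP1": 21.629,
    "kP2": 0.044433,
    "kDP": 3.6,
    "kRE": 180,
    "kkE": 79.962,
    "kkM": 1.0234,
    "kkCD": 0.03,
    "kkCE": 0.93132,
    "kCDS": 4.9260,
    "kR": 0.012490,
    "kb": 0.000013559,
    "KM": 0.15,
    "KCD": 0.92,
    "KRP": 0.01,
    "KS": 0.50,
    "KE": 155.54,
    "KCE": 0.92
  }
}
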