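{
  "name": "opt1",
  "provenance": "opt1",
  "description": "First optimization round: the 12 free parameters re-fitted, the remaining 12 held at their original values.",
  "parameters": {
    "dMC": 0.70,
    "dE": 0.25,
    "dCD": 1.5,
    "dCE": 1.5,
    "dR": 0.06,
    "dRE": 0.03,
    "dRP": 0.0039885,
    "kP1": 18,
    "kP2": 18,
    "kDP": 3.6,
    "kRE": 8.1647,
    "kkE": 19.977,
    "kkM": 0.081606,
    "kkCD": 0.20762,
    "kkCE": 1.1414,
    "kCDS": 4.9113,
    "kR": 0.013629,
    "kb": 0.0000090144,
    "KM": 0.15,
    "KCD": 0.92,
    "KRP": 0.01,
    "KS": 0.53629,
    "KE": 19.996,
    "KCE": 18.890
  }
}
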