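{
  "name": "opt3",
  "provenance": "opt3",
  "description": "Third optimization round: the 14 globally least sensitive parameters re-fitted, the remainder held at their original values.",
  "parameters": {
    "dMC": 0.01248,
    "dE": 0.18258,
    "dCD": 1.5,
    "dCE": 4.8474,
    "dR": 0.071878,
    "dRE": 0.03,
    "dRP": 0.005211,
    "kP1": 18,
    "kP2": 18,
    "kDP": 3.6,
    "kRE": 135.66,
    "kkE": 0.4,
    "kkM": 0.017103,
    "kkCD": 4.8351,
    "kkCE": 1.6526,
    "kCDS": 4.9954,
    "kR": 0.015991,
    "kb": 0.003,
    "KM": 0.99638,
    "KCD": 0.92,
    "KRP": 0.01,
    "KS": 2.8508,
    "KE": 0.15,
    "KCE": 3.8474
  }
}
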