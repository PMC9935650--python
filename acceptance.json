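{
  "t2": {
    "value": 725.7398833801767,
    "n": 30
  },
  "t3": {
    "value": 664.147232760162,
    "n": 20
  },
  "t4": {
    "value": 0.2857912465383362,
    "n": 30
  },
  "t6": {
    "value": 17.021780303030305,
    "n": 20
  },
  "t7": {
    "value": 3.2670454545454546,
    "n": 30
  }
}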