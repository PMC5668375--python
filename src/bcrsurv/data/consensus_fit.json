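{
  "d1": 0.01435,
  "k1": 0.02980,
  "k2": 2.779,
  "k3": 3.145,
  "k4": 0.1294,
  "d2": 0.1543,
  "offset": 0.6097,
  "deadline": 0.01032
}
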