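{
  "conserved": [66, 349],
  "TM1": [66, 98],
  "TM2": [103, 133],
  "TM3": [138, 173],
  "TM4": [182, 207],
  "TM5": [226, 264],
  "TM6": [270, 308],
  "TM7": [313, 338]
}
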