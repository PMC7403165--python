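SR+CS_B+:
  simpleGPC: &id001
    short: 0.8
    long: 0.2
  SR: &id003
    short: 0.95
    long: 0.05
  CS_B: &id002
    short: 0.93
    long: 0.07
SR-CS_B+:
  simpleGPC: *id001
  SR: &id004
    short: 0.1
    long: 0.9
  CS_B: *id002
SR+CS_B-:
  simpleGPC: *id001
  SR: *id003
  CS_B: &id005
    short: 0.08
    long: 0.92
SR-CS_B-:
  simpleGPC: *id001
  SR: *id004
  CS_B: *id005
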