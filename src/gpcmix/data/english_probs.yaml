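CS_O+CS_B+:
  simpleGPC: &id001
    ae: 0.88
    open_o: 0.05
    long_o: 0.03
  CS_O: &id003
    ae: 0.82
    open_o: 0.08
    long_o: 0.04
  CS_B: &id002
    ae: 0.86
    open_o: 0.06
    long_o: 0.03
CS_O-CS_B+:
  simpleGPC: *id001
  CS_O: &id004
    ae: 0.12
    open_o: 0.76
    long_o: 0.06
  CS_B: *id002
CS_O+CS_B-:
  simpleGPC: *id001
  CS_O: *id003
  CS_B: &id005
    ae: 0.1
    open_o: 0.14
    long_o: 0.7
CS_O-CS_B-:
  simpleGPC: *id001
  CS_O: *id004
  CS_B: *id005
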