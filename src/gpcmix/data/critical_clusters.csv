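cluster,frequency,consistency,entropy,group
alC,69,0.61,0.46,shared
ead,14,0.57,0.3,earlier_only
ild,6,0.5,0.3,earlier_only
ind,9,0.89,0.15,earlier_only
old,10,1,0,earlier_only
olt,5,1,0,earlier_only
ook,12,0.92,0.12,earlier_only
qua,17,0.71,0.35,shared
wa,45,0.56,0.48,shared
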