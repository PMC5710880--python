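group,P,A,N,X
Group5,107,8,3,0
lymphoma,5,0,0,0
carcinoid,1,0,1,0
Group4,0,0,0,0
Group3,25,26,0,0
Group2,0,0,1,0
Group1,12,31,31,0
GroupX,0,0,0,0
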