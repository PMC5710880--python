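group,P,A,N,X
Group5,112,0,0,0
lymphoma,8,3,6,0
carcinoid,0,0,0,0
Group4,0,0,0,0
Group3,338,385,80,7
Group2,0,0,0,0
Group1,16,28,94,0
GroupX,0,0,0,0
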