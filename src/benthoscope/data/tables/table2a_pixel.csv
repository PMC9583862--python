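,ZM,ZJ,GA,BA,NV,Total
ZM,1364,83,43,3,253,1746
ZJ,912,178,43,5,280,1418
GA,550,79,36,2,32,699
BA,33,2,1,20,39,95
NV,380,100,23,2,537,1042
Total,3239,442,146,32,1141,5000
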