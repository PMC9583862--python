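,ZM,ZJ,GA,BA,RA,SD,Total
ZM,18,2,1,0,2,1,24
ZJ,0,7,0,0,0,0,7
GA,0,0,3,0,0,0,3
BA,0,0,0,1,0,0,1
RA,0,0,0,0,0,0,0
SD,0,2,0,0,1,4,7
Total,18,11,4,1,3,5,42
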