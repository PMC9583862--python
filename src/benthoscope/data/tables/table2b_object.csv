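,ZM,ZJ,GA,BA,NV,Total
ZM,3137,387,124,14,691,4353
ZJ,16,9,3,1,23,52
GA,37,5,12,0,2,56
BA,3,0,0,11,1,15
NV,46,41,7,6,424,524
Total,3239,442,146,32,1141,5000
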