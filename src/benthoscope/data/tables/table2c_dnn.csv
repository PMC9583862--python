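,ZM,ZJ,GA,BA,NV,Total
ZM,3160,145,45,9,312,3671
ZJ,11,225,6,0,149,391
GA,4,6,17,0,6,33
BA,6,0,10,16,3,35
NV,58,66,68,7,671,870
Total,3239,442,146,32,1141,5000
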