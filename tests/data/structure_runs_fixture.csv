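K,replicate,lnP
1,1,-5000
1,2,-5010
1,3,-4990
2,1,-4500
2,2,-4510
2,3,-4490
3,1,-4300
3,2,-4310
3,3,-4290
4,1,-4250
4,2,-4260
4,3,-4240
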