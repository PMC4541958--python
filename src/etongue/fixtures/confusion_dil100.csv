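expected,XiuShui134,XiuShui128,JiaHe218,JiaHe66
XiuShui134,3,4,8,5
XiuShui128,4,1,5,10
JiaHe218,11,3,1,5
JiaHe66,3,12,4,1
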