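expected,XiuShui134,XiuShui128,JiaHe218,JiaHe66
XiuShui134,18,0,2,0
XiuShui128,1,16,0,3
JiaHe218,2,0,17,1
JiaHe66,0,2,1,17
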