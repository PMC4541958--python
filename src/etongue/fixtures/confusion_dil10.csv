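expected,XiuShui134,XiuShui128,JiaHe218,JiaHe66
XiuShui134,10,3,7,0
XiuShui128,0,7,6,7
JiaHe218,6,0,10,4
JiaHe66,0,8,3,9
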