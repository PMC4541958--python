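expected,XiuShui134,XiuShui128,JiaHe218,JiaHe66
XiuShui134,20,0,0,0
XiuShui128,0,18,0,2
JiaHe218,1,0,19,0
JiaHe66,0,1,0,19
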