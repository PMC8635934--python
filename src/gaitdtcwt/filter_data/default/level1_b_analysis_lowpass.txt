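0
-0.17677669529663689
0.35355339059327379
1.0606601717798214
0.35355339059327379
-0.17677669529663689
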