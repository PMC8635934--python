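0
0
0
0.35355339059327373
-0.70710678118654746
0.35355339059327373
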