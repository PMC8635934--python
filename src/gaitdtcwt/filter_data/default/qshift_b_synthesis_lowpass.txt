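-0.0035377531797870405
0.0012549056800159591
0.012975958744507769
0.033190114137043696
-0.12629969414091605
0.018101564304778134
0.579509304121822
0.73256570615388716
0.29897347018293302
-0.12301742626220938
-0.052174196727164168
0.051609569526915595
-0.0023403078148482061
-0.0065976523538840053
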