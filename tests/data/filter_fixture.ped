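FIX gf 0 0 1 0
FIX gm 0 0 2 0
FIX p1 gf gm 2 0
FIX p2 gf gm 2 0
FIX sp1 0 0 1 0
FIX sp2 0 0 1 0
FIX c1 sp1 p1 1 2
FIX c2 sp2 p2 1 2
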