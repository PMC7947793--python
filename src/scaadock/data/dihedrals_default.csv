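position,phi,psi,omega
1,-139.0,135.0,180.0
2,-139.0,135.0,180.0
3,-139.0,135.0,180.0
4,-139.0,135.0,180.0
5,-139.0,135.0,180.0
6,-139.0,135.0,180.0
7,-139.0,135.0,180.0
8,-139.0,135.0,180.0
9,-139.0,135.0,180.0
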