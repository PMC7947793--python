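natural_code,scaa_code
A,V
C,S
D,D
E,D
F,Y
G,V
H,H
I,V
K,H
L,V
M,V
N,Q
P,V
Q,Q
R,H
S,S
T,S
V,V
W,Y
Y,Y
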