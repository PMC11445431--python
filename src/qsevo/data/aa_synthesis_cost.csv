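# Amino-acid synthesis costs in high-energy phosphate bonds (~P) in E. coli,
# after Akashi & Gojobori (2002, PNAS 99:3695), expressed in whole phosphate
# bonds so the canonical range runs from 11 (Ala/Gly/Ser) to 74 (Trp).
aa,pbonds
A,11
R,27
N,14
D,12
C,24
Q,16
E,15
G,11
H,38
I,32
L,27
K,30
M,34
F,52
P,20
S,11
T,18
W,74
Y,50
V,23
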