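# Average residue masses in Daltons, water-subtracted (i.e. the mass each
# residue contributes inside a peptide chain). Standard IUPAC average values.
aa,mass
G,57.0519
A,71.0788
S,87.0782
P,97.1167
V,99.1326
T,101.1051
C,103.1388
L,113.1594
I,113.1594
N,114.1038
D,115.0886
Q,128.1307
K,128.1741
E,129.1155
M,131.1926
H,137.1411
F,147.1766
R,156.1875
Y,163.1760
W,186.2132
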