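# Apolar side-chain atoms: carbons with no bonded O/N neighbour, plus the
# thioether sulfur of methionine.
aa	atoms
A	CB
R	CB|CG|CD
N	CB
D	CB
C	CB
Q	CB|CG
E	CB|CG
G
H	CB
I	CB|CG1|CG2|CD1
L	CB|CG|CD1|CD2
K	CB|CG|CD
M	CB|CG|SD|CE
F	CB|CG|CD1|CD2|CE1|CE2|CZ
P	CB|CG
S
T	CG2
W	CB|CG|CD2|CE3|CZ2|CZ3|CH2
Y	CB|CG|CD1|CD2|CE1|CE2
V	CB|CG1|CG2
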