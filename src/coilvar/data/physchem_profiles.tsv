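residue	structural_class	hydropathy	charge
A	aliphatic	hydrophobic	neutral
R	polar	hydrophilic	positive
N	polar	hydrophilic	neutral
D	polar	hydrophilic	negative
C	special	hydrophobic	neutral
E	polar	hydrophilic	negative
Q	polar	hydrophilic	neutral
G	special	hydrophilic	neutral
H	polar	hydrophilic	neutral
I	aliphatic	hydrophobic	neutral
L	aliphatic	hydrophobic	neutral
K	polar	hydrophilic	positive
M	aliphatic	hydrophobic	neutral
F	aromatic	hydrophobic	neutral
P	special	hydrophobic	neutral
S	polar	hydrophilic	neutral
T	polar	hydrophilic	neutral
W	aromatic	hydrophobic	neutral
Y	aromatic	hydrophobic	neutral
V	aliphatic	hydrophobic	neutral
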