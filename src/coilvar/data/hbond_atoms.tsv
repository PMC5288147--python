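# Side-chain hydrogen-bond donors and acceptors with the donor antecedent
# atom used for the heavy-atom angle criterion.  Main-chain N (donor,
# antecedent CA) and O (acceptor) are handled in code.
aa	atom	role	antecedent
R	NE	donor	CD
R	NH1	donor	CZ
R	NH2	donor	CZ
N	ND2	donor	CG
N	OD1	acceptor	-
D	OD1	acceptor	-
D	OD2	acceptor	-
C	SG	donor	CB
Q	NE2	donor	CD
Q	OE1	acceptor	-
E	OE1	acceptor	-
E	OE2	acceptor	-
H	ND1	both	CG
H	NE2	both	CD2
K	NZ	donor	CE
M	SD	acceptor	-
S	OG	both	CB
T	OG1	both	CB
W	NE1	donor	CD1
Y	OH	both	CZ
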