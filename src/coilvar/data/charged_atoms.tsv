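# Charged-group atoms for salt-bridge detection.  Histidine ring nitrogens
# are listed with sign '+h' and only used when the criteria enable them.
aa	atom	sign
D	OD1	-
D	OD2	-
E	OE1	-
E	OE2	-
K	NZ	+
R	NE	+
R	NH1	+
R	NH2	+
H	ND1	+h
H	NE2	+h
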