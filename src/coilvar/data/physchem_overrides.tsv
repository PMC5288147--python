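# Literal label overrides used when rendering published-table style strings.
# The canonical profile table stays chemically standard; these reproduce the
# exact wording of the source variant table for the affected residues.
residue	literal
Y	Aliphatic, Hydrophobic, Polar
P	Hydrophobic, Neutral
C	Polar, Hydrophilic, Neutral
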