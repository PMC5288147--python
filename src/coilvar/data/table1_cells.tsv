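gene	protein	wt_literal	mut_literal
K1	p.L437P	Aliphatic, Hydrophobic, Neutral	Hydrophobic, Neutral
K1	p.E478K	Polar, Hydrophilic, Charged(-)	Polar, Hydrophilic, Charged(+)
K1	p.E478Q	Polar, Hydrophilic, Charged(-)	Polar, Hydrophilic, Neutral
K1	p.E478D	Polar, Hydrophilic, Charged(-)	Polar, Hydrophilic, Charged(-)
K1	p.I479F	Aliphatic, Hydrophobic, Neutral	Aromatic, Hydrophobic, Neutral
K1	p.I479T	Aliphatic, Hydrophobic, Neutral	Polar, Hydrophilic, Neutral
K1	p.T481P	Polar, Hydrophilic, Neutral	Hydrophobic, Neutral
K1	p.Y482C	Aliphatic, Hydrophobic, Polar	Polar, Hydrophilic, Neutral
K1	p.L485P	Aliphatic, Hydrophobic, Neutral	Hydrophobic, Neutral
K1	p.L486P	Aliphatic, Hydrophobic, Neutral	Hydrophobic, Neutral
K1	p.L486R	Aliphatic, Hydrophobic, Neutral	Polar, Hydrophilic, Charged(+)
K10	p.K439E	Polar, Hydrophilic, Charged(+)	Polar, Hydrophilic, Charged(-)
K10	p.L442Q	Aliphatic, Hydrophobic, Neutral	Polar, Hydrophilic, Neutral
K10	p.E445K	Polar, Hydrophilic, Charged(-)	Polar, Hydrophilic, Charged(+)
K10	p.I446T	Aliphatic, Hydrophobic, Neutral	Polar, Hydrophilic, Neutral
K10	p.Q447P	Polar, Hydrophilic, Neutral	Hydrophobic, Neutral
K10	p.Y449D	Aliphatic, Hydrophobic, Polar	Polar, Hydrophilic, Charged(-)
K10	p.Y449C	Aliphatic, Hydrophobic, Polar	Polar, Hydrophilic, Neutral
K10	p.R450P	Polar, Hydrophilic, Charged(+)	Hydrophobic, Neutral
K10	p.L452P	Aliphatic, Hydrophobic, Neutral	Hydrophobic, Neutral
K10	p.L453P	Aliphatic, Hydrophobic, Neutral	Hydrophobic, Neutral
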