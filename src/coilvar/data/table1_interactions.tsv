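# Lost-partner sets transcribed from the published per-variant interaction
# table.  Partners are gene-qualified residue numbers separated by '|'.
gene	protein	lost_hydrophobic	lost_hbond
K1	p.L437P	K10:403|K10:404
K1	p.E478K		K10:450
K1	p.E478Q		K10:450
K1	p.E478D		K10:450
K1	p.I479F	K10:442|K10:445|K10:446
K1	p.I479T	K10:442|K10:445|K10:446
K1	p.T481P
K1	p.Y482C	K10:446|K10:450	K10:450
K1	p.L485P	K10:453
K1	p.L486P	K10:449|K10:453
K1	p.L486R	K10:449|K10:453
K10	p.K439E	K1:468|K1:471|K1:475	K10:443
K10	p.L442Q	K1:472|K1:475|K1:476|K1:479
K10	p.E445K	K1:479
K10	p.I446T	K1:478|K1:479|K1:482
K10	p.Q447P
K10	p.Y449D	K1:486
K10	p.Y449C
K10	p.R450P		K1:478|K1:482
K10	p.L452P	K1:486
K10	p.L453P	K1:486
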