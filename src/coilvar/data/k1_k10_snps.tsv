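gene	cdna	protein	category	diseases	severity
K1	c.1207C>T	p.R403C	snp	none	n/a
K1	c.1284T>G	p.D428E	snp	none	n/a
K1	c.1293G>C	p.Q431H	snp	none	n/a
K1	c.1294C>T	p.R432C	snp	none	n/a
K1	c.1295G>A	p.R432H	snp	none	n/a
K1	c.1304A>T	p.N435I	snp	none	n/a
K1	c.1316A>G	p.D439G	snp	none	n/a
K1	c.1349C>G	p.A450G	snp	none	n/a
K1	c.1369G>T	p.D457Y	snp	none	n/a
K1	c.1388G>A	p.R463H	snp	none	n/a
K1	c.1390G>A	p.D464N	snp	none	n/a
K10	c.1140G>C	p.Q380H	snp	none	n/a
K10	c.1196G>A	p.R399H	snp	none	n/a
K10	c.1228C>G	p.Q410E	snp	none	n/a
K10	c.1258C>G	p.Q420E	snp	none	n/a
K10	c.1260G>C	p.Q420H	snp	none	n/a
K10	c.1327G>A	p.E443K	snp	none	n/a
K10	c.1348C>T	p.R450C	snp	none	n/a
K10	c.1351A>G	p.S451G	snp	none	n/a
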