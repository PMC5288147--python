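gene	cdna	protein	category	diseases	severity
K1	c.1310T>C	p.L437P	disease_mutation	NEPPK	mild
K1	c.1432G>A	p.E478K	disease_mutation	BCIE/EHK	moderate
K1	c.1432G>C	p.E478Q	disease_mutation	CIEH	moderate
K1	c.1434G>T	p.E478D	disease_mutation	BCIE/EHK	mild
K1	c.1435A>T	p.I479F	disease_mutation	BCIE/EHK	moderate
K1	c.1436T>C	p.I479T	disease_mutation	BCIE/EHK|CIEH	moderate
K1	c.1441A>C	p.T481P	disease_mutation	BCIE/EHK	moderate
K1	c.1445A>G	p.Y482C	disease_mutation	BCIE/EHK	moderate
K1	c.1454T>C	p.L485P	disease_mutation	CIEH	moderate
K1	c.1457T>C	p.L486P	disease_mutation	BCIE/EHK|CIEH	moderate
K1	c.1457T>G	p.L486R	disease_mutation	BCIE/EHK	severe
K10	c.1315A>G	p.K439E	disease_mutation	BCIE/EHK	mild
K10	c.1325T>A	p.L442Q	disease_mutation	BCIE/EHK	moderate
K10	c.1333G>A	p.E445K	disease_mutation	BCIE/EHK	severe
K10	c.1337T>C	p.I446T	disease_mutation	CIEH	severe
K10	c.1340A>C	p.Q447P	disease_mutation	BCIE/EHK	mild
K10	c.1345T>G	p.Y449D	disease_mutation	BCIE/EHK	mild
K10	c.1346A>G	p.Y449C	disease_mutation	CIEH	mild
K10	c.1349G>C	p.R450P	disease_mutation	BCIE/EHK	unknown
K10	c.1355T>C	p.L452P	disease_mutation	BCIE/EHK	severe
K10	c.1358T>C	p.L453P	disease_mutation	BCIE/EHK	severe
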