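# Backbone-independent rotamer bin frequencies, three bins per rotatable chi
# (m = -60, t = 180, p = +60).  A rotamer's probability is the product of its
# per-chi bin frequencies; bins of one chi sum to 1 so the library normalizes
# exactly.  Residues with no rotatable chi (A, G, P) get one null rotamer.
aa	chi	m	t	p
R	1	0.52	0.35	0.13
R	2	0.30	0.55	0.15
R	3	0.35	0.45	0.20
R	4	0.35	0.40	0.25
N	1	0.52	0.35	0.13
N	2	0.30	0.55	0.15
D	1	0.52	0.35	0.13
D	2	0.30	0.55	0.15
C	1	0.52	0.35	0.13
Q	1	0.52	0.35	0.13
Q	2	0.30	0.55	0.15
Q	3	0.35	0.45	0.20
E	1	0.52	0.35	0.13
E	2	0.30	0.55	0.15
E	3	0.35	0.45	0.20
H	1	0.52	0.35	0.13
H	2	0.30	0.55	0.15
I	1	0.60	0.25	0.15
I	2	0.30	0.55	0.15
L	1	0.52	0.35	0.13
L	2	0.24	0.63	0.13
K	1	0.52	0.35	0.13
K	2	0.30	0.55	0.15
K	3	0.35	0.45	0.20
K	4	0.35	0.40	0.25
M	1	0.52	0.35	0.13
M	2	0.30	0.55	0.15
M	3	0.35	0.45	0.20
F	1	0.52	0.35	0.13
F	2	0.30	0.55	0.15
S	1	0.29	0.23	0.48
T	1	0.43	0.08	0.49
W	1	0.52	0.35	0.13
W	2	0.30	0.55	0.15
Y	1	0.52	0.35	0.13
Y	2	0.30	0.55	0.15
V	1	0.20	0.73	0.07
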