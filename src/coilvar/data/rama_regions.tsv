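# Ramachandran region boxes (degrees).  A residue is classified by the best
# tier whose box contains its (phi, psi); outside all boxes -> disallowed.
# The glycine map adds the phi>0 mirror regions.
map	tier	phi_min	phi_max	psi_min	psi_max
general	core	-105	-30	-80	5
general	core	-170	-60	100	175
general	allowed	-155	-5	-105	45
general	allowed	-180	-40	80	180
general	allowed	-180	-40	-180	-160
general	allowed	30	90	0	70
general	generous	-175	15	-125	65
general	generous	-180	-20	60	180
general	generous	-180	-20	-180	-140
general	generous	10	110	-20	90
glycine	core	-105	-30	-80	5
glycine	core	-170	-60	100	175
glycine	core	30	105	-5	80
glycine	allowed	-155	-5	-105	45
glycine	allowed	-180	-40	80	180
glycine	allowed	-180	-40	-180	-160
glycine	allowed	20	140	-35	95
glycine	allowed	60	180	-180	-100
glycine	allowed	40	180	100	180
glycine	generous	-175	15	-125	65
glycine	generous	-180	-20	60	180
glycine	generous	-180	-20	-180	-140
glycine	generous	0	160	-55	115
glycine	generous	20	180	-180	-80
glycine	generous	20	180	80	180
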