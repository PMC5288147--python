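# Classic Clustal strong and weak amino-acid substitution groups.
strength	members
strong	STA
strong	NEQK
strong	NHQK
strong	NDEQ
strong	QHRK
strong	MILV
strong	MILF
strong	HY
strong	FYW
weak	CSA
weak	ATV
weak	SAG
weak	STNK
weak	STPA
weak	SGND
weak	SNDEQK
weak	NDEQHK
weak	NEQHRK
weak	FVLIM
weak	HFY
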