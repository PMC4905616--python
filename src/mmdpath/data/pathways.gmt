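catabolism	fatty acid catabolism pathway	PECI	PMDCI	HPNCL	AOX	BIEN	THIOL	CACP	CPT2	Tpalpha	Tpbeta	mHMGCoAS	CYP4A10	CYP4A14	ACBP	L.FABP	ACOTH	PLTP
omega3	long-chain omega-3 fatty acids	C20.5n.3	C22.5n.3	C22.6n.3
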