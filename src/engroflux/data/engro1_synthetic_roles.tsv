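# role	reaction id (synthetic ENGRO1 reconstruction)
aconitase	ACONT
pdh	PDH
lactate_efflux	EX_lac
glucose_uptake	EX_glc
glutamine_uptake	EX_gln
oxygen_uptake	EX_o2
ammonia_efflux	EX_nh3
atp_maintenance	ATPM
complex_i	CPLX1
complex_ii	CPLX2
idh_nad	ICDH_NAD
idh_nadp	ICDH_NADP
malic_enzyme_nad	ME_NAD
malic_enzyme_nadp	ME_NADP
malate_dehydrogenase	MDH
pep_carboxykinase	PEPCK
gdh_nad	GDH_NAD
gdh_nadp	GDH_NADP
biomass	BIOMASS
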