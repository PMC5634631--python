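# Catabolic route definitions over the synthetic core-network reconstruction.
# One line per (route, reaction); respiration (CPLX1/CPLX2) is accounted
# analytically by the yield module and must not appear here.
route_id	reaction_id	multiplier
glc_to_lactate	HEX1	1
glc_to_lactate	PGI	1
glc_to_lactate	PFK	1
glc_to_lactate	FBA	1
glc_to_lactate	TPI	1
glc_to_lactate	GAPD	2
glc_to_lactate	PGK	2
glc_to_lactate	ENO	2
glc_to_lactate	PYK	2
glc_to_lactate	LDH	2
glc_to_pyruvate	HEX1	1
glc_to_pyruvate	PGI	1
glc_to_pyruvate	PFK	1
glc_to_pyruvate	FBA	1
glc_to_pyruvate	TPI	1
glc_to_pyruvate	GAPD	2
glc_to_pyruvate	PGK	2
glc_to_pyruvate	ENO	2
glc_to_pyruvate	PYK	2
glc_respiration	HEX1	1
glc_respiration	PGI	1
glc_respiration	PFK	1
glc_respiration	FBA	1
glc_respiration	TPI	1
glc_respiration	GAPD	2
glc_respiration	PGK	2
glc_respiration	ENO	2
glc_respiration	PYK	2
glc_respiration	PDH	2
glc_respiration	CS	2
glc_respiration	ACONT	2
glc_respiration	ICDH_NAD	2
glc_respiration	AKGD	2
glc_respiration	SUCOAS	2
glc_respiration	SUCD	2
glc_respiration	FUM	2
glc_respiration	MDH	2
glc_to_accoa	HEX1	1
glc_to_accoa	PGI	1
glc_to_accoa	PFK	1
glc_to_accoa	FBA	1
glc_to_accoa	TPI	1
glc_to_accoa	GAPD	2
glc_to_accoa	PGK	2
glc_to_accoa	ENO	2
glc_to_accoa	PYK	2
glc_to_accoa	PDH	2
glc_to_accoa	CS	2
glc_to_accoa	ACL	2
gln_to_lactate	GLS	1
gln_to_lactate	GDH_NAD	1
gln_to_lactate	AKGD	1
gln_to_lactate	SUCOAS	1
gln_to_lactate	SUCD	1
gln_to_lactate	FUM	1
gln_to_lactate	ME_NAD	1
gln_to_lactate	LDH	1
gln_to_pyruvate	GLS	1
gln_to_pyruvate	GDH_NAD	1
gln_to_pyruvate	AKGD	1
gln_to_pyruvate	SUCOAS	1
gln_to_pyruvate	SUCD	1
gln_to_pyruvate	FUM	1
gln_to_pyruvate	ME_NAD	1
gln_respiration	GLS	1
gln_respiration	GDH_NAD	1
gln_respiration	AKGD	2
gln_respiration	SUCOAS	2
gln_respiration	SUCD	2
gln_respiration	FUM	2
gln_respiration	ME_NAD	1
gln_respiration	MDH	1
gln_respiration	PDH	1
gln_respiration	CS	1
gln_respiration	ACONT	1
gln_respiration	ICDH_NAD	1
gln_to_accoa_reductive	GLS	1
gln_to_accoa_reductive	GDH_NADP	1
gln_to_accoa_reductive	ICDH_NADP	-1
gln_to_accoa_reductive	ACONT	-1
gln_to_accoa_reductive	ACL	1
gln_to_accoa_reductive	MDH	-1
gln_to_accoa_reductive	ME_NAD	1
gln_to_accoa_reductive	LDH	1
gln_to_accoa_clockwise	GLS	1
gln_to_accoa_clockwise	GDH_NAD	1
gln_to_accoa_clockwise	AKGD	1
gln_to_accoa_clockwise	SUCOAS	1
gln_to_accoa_clockwise	SUCD	1
gln_to_accoa_clockwise	FUM	1
gln_to_accoa_clockwise	ME_NAD	1
gln_to_accoa_clockwise	PDH	1
gln_to_accoa_clockwise	CS	1
gln_to_accoa_clockwise	ACL	1
gln_to_two_accoa_combined	GLS	1
gln_to_two_accoa_combined	GDH_NADP	1
gln_to_two_accoa_combined	ICDH_NADP	-1
gln_to_two_accoa_combined	ACONT	-1
gln_to_two_accoa_combined	ACL	2
gln_to_two_accoa_combined	MDH	-1
gln_to_two_accoa_combined	ME_NAD	1
gln_to_two_accoa_combined	PDH	1
gln_to_two_accoa_combined	CS	1
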