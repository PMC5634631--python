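# Synthetic reconstruction of the ENGRO1 core glucose/glutamine network
# (84 reactions, 67 metabolites). This file is a stand-in rebuilt from the
# published pathway inventory and calibrated to documented operating
# points; it is NOT the original supplementary model file.
# pROS (Complex I electron fraction to superoxide) baked into CPLX1: 0.25
id	name	equation	lower_bound	upper_bound	pathway
HEX1	hexokinase	glc + atp => g6p + adp	0	1000	glycolysis
PGI	phosphoglucose isomerase	g6p <=> f6p	-1000	1000	glycolysis
PFK	phosphofructokinase	f6p + atp => fdp + adp	0	1000	glycolysis
FBA	fructose-bisphosphate aldolase	fdp <=> dhap + g3p	-1000	1000	glycolysis
TPI	triose-phosphate isomerase	dhap <=> g3p	-1000	1000	glycolysis
GAPD	glyceraldehyde-3P dehydrogenase	g3p + nad + pi <=> 13dpg + nadh	-1000	1000	glycolysis
PGK	phosphoglycerate kinase	13dpg + adp <=> 3pg + atp	-1000	1000	glycolysis
ENO	phosphoglycerate mutase + enolase	3pg <=> pep	-1000	1000	glycolysis
PYK	pyruvate kinase	pep + adp => pyr + atp	0	1000	glycolysis
LDH	lactate dehydrogenase	pyr + nadh <=> lac + nad	-1000	1000	glycolysis
PDH	pyruvate dehydrogenase	pyr + nad => accoa + co2 + nadh	0	1000	tca
CS	citrate synthase	accoa + oaa => cit	0	1000	tca
ACONT	aconitase	cit <=> icit	-1000	1000	tca
ICDH_NAD	isocitrate dehydrogenase (NAD)	icit + nad <=> akg + co2 + nadh	-1000	1000	tca
AKGD	alpha-ketoglutarate dehydrogenase	akg + nad => succoa + co2 + nadh	0	1000	tca
SUCOAS	succinyl-CoA synthetase	succoa + adp + pi <=> succ + atp	-1000	1000	tca
SUCD	succinate dehydrogenase	succ + fad => fum + fadh2	0	1000	tca
FUM	fumarase	fum <=> mal	-1000	1000	tca
MDH	malate dehydrogenase	mal + nad <=> oaa + nadh	-1000	1000	tca
CPLX1	NADH oxidation (Complex I chain, ROS-generating)	nadh + 0.625 o2 + 2.25 adp + 2.25 pi => nad + 2.25 atp + 0.25 h2o2	0	1000	oxphos
CPLX2	FADH2 oxidation (Complex II chain)	fadh2 + 0.5 o2 + 2 adp + 2 pi => fad + 2 atp	0	1000	oxphos
GLS	glutaminase	gln => glu + nh3	0	1000	glutamine
GDH_NAD	glutamate dehydrogenase (NAD)	glu + nad => akg + nh3 + nadh	0	1000	glutamine
GDH_NADP	glutamate dehydrogenase (NADP)	glu + nadp => akg + nh3 + nadph	0	1000	glutamine
ICDH_NADP	isocitrate dehydrogenase (NADP)	icit + nadp <=> akg + co2 + nadph	-1000	1000	glutamine
CPS1	carbamoyl-phosphate synthetase	nh3 + co2 + 2 atp => cbp + 2 adp + pi	0	1000	urea
OTC	ornithine transcarbamylase	orn + cbp => citr + pi	0	1000	urea
ASS	argininosuccinate synthase	citr + asp + atp => argsuc + adp + pi	0	1000	urea
ASL	argininosuccinate lyase	argsuc <=> arg + fum	-1000	1000	urea
ARGN	arginase	arg => orn + urea	0	1000	urea
GLUCYS_S	glutamate-cysteine ligase	glu + cys + atp => glucys + adp + pi	0	1000	glutathione
GSHS	glutathione synthetase	glucys + gly + atp => gsh + adp + pi	0	1000	glutathione
GPX	glutathione peroxidase	2 gsh + h2o2 => gssg	0	1000	glutathione
GR	glutathione reductase	gssg + nadph => 2 gsh + nadp	0	1000	glutathione
DM_H2O2	hydrogen peroxide demand	h2o2 =>	0	1000	glutathione
METHCY	methionine demethylation (lumped)	met => hcys + for	0	1000	glutathione
CBS	cystathionine beta-synthase	hcys + ser => cyst	0	1000	glutathione
CTH	cystathionine gamma-lyase	cyst => cys + nh3 + obut	0	1000	glutathione
OBDH	2-oxobutanoate to succinyl-CoA (lumped)	obut + nad + atp => succoa + nadh + adp + pi	0	1000	glutathione
MS	methionine synthase	hcys + mlthf => met + thf	0	1000	glutathione
ACL	ATP-citrate lyase	cit + atp => accoa_c + oaa + adp + pi	0	1000	fatty acid
FAS	palmitate synthesis (lumped)	8 accoa_c + 14 nadph + 7 atp => palm + 14 nadp + 7 adp + 7 pi	0	1000	fatty acid
G6PD	oxidative PPP (lumped)	g6p + 2 nadp => ru5p + co2 + 2 nadph	0	1000	ppp
RPI	ribose-5P isomerase	ru5p <=> r5p	-1000	1000	ppp
RPE	ribulose-5P epimerase	ru5p <=> x5p	-1000	1000	ppp
TKT1	transketolase/transaldolase (lumped 1)	x5p + r5p <=> f6p + e4p	-1000	1000	ppp
TKT2	transketolase (lumped 2)	x5p + e4p <=> f6p + g3p	-1000	1000	ppp
SERS	serine synthesis (lumped)	3pg + glu + nad => ser + akg + nadh + pi	0	1000	amino acid
GHMT	serine hydroxymethyltransferase	ser + thf <=> gly + mlthf	-1000	1000	amino acid
MTHFD	methylene-THF dehydrogenase (NADP)	mlthf + nadp => for + thf + nadph	0	1000	amino acid
ALT	alanine transaminase	pyr + glu <=> ala + akg	-1000	1000	amino acid
AST	aspartate transaminase	oaa + glu <=> asp + akg	-1000	1000	amino acid
ASNS	asparagine synthetase	asp + gln + atp => asn + glu + adp + pi	0	1000	amino acid
ASNASE	asparaginase	asn => asp + nh3	0	1000	amino acid
PROS_NADH	proline synthesis (NADH)	glu + atp + 2 nadh => pro + adp + pi + 2 nad	0	1000	amino acid
PROS_NADPH	proline synthesis (NADPH)	glu + atp + 2 nadph => pro + adp + pi + 2 nadp	0	1000	amino acid
CYSS	cysteine synthesis (lumped; sulfur not tracked)	ser => cys	0	1000	amino acid
GLYCL	glycine cleavage	gly + thf + nad => mlthf + co2 + nh3 + nadh	0	1000	amino acid
ORNS	ornithine synthesis (lumped)	2 glu + atp + nadh => orn + akg + adp + pi + nad	0	1000	amino acid
ODC	ornithine decarboxylase	orn => ptrc + co2	0	1000	amino acid
PEPCK	PEP carboxykinase	oaa + atp => pep + co2 + adp	0	1000	anaplerosis
PC	pyruvate carboxylase	pyr + co2 + atp => oaa + adp + pi	0	1000	anaplerosis
ME_NAD	malic enzyme (NAD)	mal + nad => pyr + co2 + nadh	0	1000	anaplerosis
ME_NADP	malic enzyme (NADP)	mal + nadp => pyr + co2 + nadph	0	1000	anaplerosis
ATPM	ATP maintenance	atp => adp + pi	0	1000	maintenance
PROT_50A50B	protein synthesis, standard NEAA mix	0.125 ser + 0.125 gly + 0.125 cys + 0.125 ala + 0.08333333333 asp + 0.08333333333 asn + 0.08333333333 glu + 0.08333333333 gln + 0.08333333333 arg + 0.08333333333 pro + 4 atp => protein + 4 adp + 4 pi	0	1000	protein synthesis
PROT_80A20B	protein synthesis, 80/20 NEAA mix	0.2 ser + 0.2 gly + 0.2 cys + 0.2 ala + 0.03333333333 asp + 0.03333333333 asn + 0.03333333333 glu + 0.03333333333 gln + 0.03333333333 arg + 0.03333333333 pro + 4 atp => protein + 4 adp + 4 pi	0	0	protein synthesis
PROT_20A80B	protein synthesis, 20/80 NEAA mix	0.05 ser + 0.05 gly + 0.05 cys + 0.05 ala + 0.1333333333 asp + 0.1333333333 asn + 0.1333333333 glu + 0.1333333333 gln + 0.1333333333 arg + 0.1333333333 pro + 4 atp => protein + 4 adp + 4 pi	0	0	protein synthesis
BIOMASS	biomass assembly	6 protein + 0.37 palm + 0.05 gsh + 65.206 atp => biomass + 65.206 adp + 65.206 pi	0	1000	biomass
EX_glc	glucose uptake	=> glc	0	20	exchange
EX_gln	glutamine uptake	=> gln	0	20	exchange
EX_o2	oxygen uptake	=> o2	0	20	exchange
EX_met	methionine uptake	=> met	0	1	exchange
EX_lac	lactate efflux	lac =>	0	1000	exchange
EX_nh3	ammonia efflux	nh3 =>	0	1000	exchange
EX_urea	urea efflux	urea =>	0	1000	exchange
EX_co2	CO2 efflux	co2 =>	0	1000	exchange
EX_pyr	pyruvate efflux (closed by default)	pyr =>	0	0	exchange
EX_ptrc	putrescine efflux (closed by default)	ptrc =>	0	0	exchange
EX_for	formate efflux	for =>	0	1000	exchange
EX_ala	alanine efflux (closed by default)	ala =>	0	0	exchange
EX_glu	glutamate efflux (closed by default)	glu =>	0	0	exchange
EX_ser	serine efflux (closed by default)	ser =>	0	0	exchange
EX_biomass	biomass efflux	biomass =>	0	1000	exchange
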