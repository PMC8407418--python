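# Default marker/pathway panel for the metabolic profile table.
# kind=marker rows list identifier aliases for a presence/absence flag;
# kind=pathway rows list member genes for percent completeness.
# Pathway memberships are reconstructions of commonly used definitions and
# are meant to be edited; matching is exact after case-folding.
# kind	name	member
marker	TIM	TIM
marker	TIM	tpiA
marker	TIM	EC 5.3.1.1
marker	TIM	triose phosphate isomerase
marker	GAPDH	GAPDH
marker	GAPDH	gapA
marker	GAPDH	EC 1.2.1.12
marker	GAPDH	glyceraldehyde 3-phosphate dehydrogenase
marker	PGK	PGK
marker	PGK	pgk
marker	PGK	EC 2.7.2.3
marker	PGK	phosphoglycerate kinase
marker	NADH_dehydrogenase	NADH dehydrogenase
marker	NADH_dehydrogenase	ndh
marker	NADH_dehydrogenase	nuoB
marker	NADH_dehydrogenase	EC 1.6.5.3
marker	ctaB	ctaB
marker	ctaB	heme O synthase
marker	ctaB	EC 2.5.1.141
marker	PPA	PPA
marker	PPA	ppa
marker	PPA	inorganic pyrophosphatase
marker	PPA	EC 3.6.1.1
marker	sdhA	sdhA
marker	sdhA	EC 1.3.5.1
marker	sdhA	EC 1.3.5.4
pathway	F-type ATPase	atpA
pathway	F-type ATPase	atpB
pathway	F-type ATPase	atpC
pathway	F-type ATPase	atpD
pathway	F-type ATPase	atpE
pathway	F-type ATPase	atpF
pathway	F-type ATPase	atpG
pathway	F-type ATPase	atpH
pathway	TCA	gltA
pathway	TCA	acnA
pathway	TCA	icd
pathway	TCA	sucA
pathway	TCA	sucB
pathway	TCA	sucC
pathway	TCA	sucD
pathway	TCA	sdhA
pathway	TCA	fumA
pathway	TCA	mdh
pathway	AA	hisD
pathway	AA	trpB
pathway	AA	argH
pathway	AA	leuB
pathway	AA	thrC
pathway	AA	ilvC
pathway	AA	metE
pathway	AA	proB
pathway	AA	serA
pathway	AA	lysA
pathway	Lip	accA
pathway	Lip	accB
pathway	Lip	accC
pathway	Lip	accD
pathway	Lip	fabD
pathway	Lip	fabF
pathway	Lip	fabG
pathway	Lip	fabH
pathway	Lip	fabZ
pathway	Lip	plsX
pathway	Pur	purA
pathway	Pur	purB
pathway	Pur	purC
pathway	Pur	purD
pathway	Pur	purE
pathway	Pur	purF
pathway	Pur	purH
pathway	Pur	purK
pathway	Pur	purL
pathway	Pur	purM
pathway	Pur	purN
pathway	Pyr	pyrB
pathway	Pyr	pyrC
pathway	Pyr	pyrD
pathway	Pyr	pyrE
pathway	Pyr	pyrF
pathway	Pyr	pyrG
pathway	Pyr	carA
pathway	Pyr	carB
pathway	Pyr	pyrH
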