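# trpcap-reference-network v1
# Synthetic curation fixture: a 12-metabolite / 10-reaction tryptophan-degradation
# network with the three canonical branches (indole, serotonin, kynurenine).
# Reactions follow real tryptophan biochemistry where practical; R06 and R09 are
# documented multi-step collapses. This file is synthetic test data, not a curated
# biological resource.
## metabolites
met_id	name	abbrev	kegg	modelseed	bigg	is_currency	origin	is_bioactive
trp	L-tryptophan	Trp	C00078	cpd00065	trp__L	0	both	0
h2o	water	H2O	C00001	cpd00001	h2o	1	both	0
nh3	ammonia	NH3	C00014	cpd00013	nh4	1	both	0
pyr	pyruvate	Pyr	C00022	cpd00020	pyr	0	both	0
indole	indole	Indole	C00463	cpd00359	indole	0	microbe	1
ipy	indole-3-pyruvate	IPY	C00331	cpd00428	indpyr	0	microbe	1
ila	indole-3-lactate	ILA	C02043	cpd03172	indlac	0	microbe	1
ia	indole-3-acrylate	IA	C22202	cpd23029	indacr	0	microbe	1
ipa	indole-3-propionate	IPA	C16666	cpd05228	ind3ppa	0	microbe	1
trpta	tryptamine	Tryptamine	C00398	cpd00412	trypta	0	both	1
iaa	indole-3-acetate	IAA	C00954	cpd00703	ind3ac	0	both	1
kyn	L-kynurenine	KYN	C00328	cpd00581	Lkynr	0	both	1
## reactions
rxn_id	substrates	products	reversible	ec_list	origin	pathway_tag	evidence_pmids
R01	trp:1;pyr:1	ipy:1	1	2.6.1.27	microbe	indole	26687352
R02	ipy:1	ila:1	1	1.1.1.110	microbe	indole	28285823
R03	ila:1	ia:1;h2o:1	0	4.2.1.-	microbe	indole	29168502
R04	ia:1	ipa:1	0	1.3.1.-	microbe	indole	29168502
R05	trp:1;h2o:1	indole:1;pyr:1;nh3:1	0	4.1.99.1	microbe	indole	20877914
R06	ipy:1	iaa:1	0	4.1.1.74	microbe	indole	26687352
R07	trp:1	trpta:1	0	4.1.1.28	both	serotonin	24997034
R08	trpta:1;h2o:1	iaa:1;nh3:1	0	1.4.3.4	microbe	serotonin	24997034
R09	trp:1;h2o:1	kyn:1	0	1.13.11.11	both	kynurenine	28602579
R10	trp:1;h2o:1	ipy:1;nh3:1	0	1.4.1.19	microbe	indole	26687352
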