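rsid	locus	chromosome	decreasing_allele	allele_freq	gamma	gamma_se	p_exposure	f_statistic	or_outcome	ci_low	ci_high	p_outcome	source_study	proxy_rsid	proxy_r2	pathway
rs10741657	CYP2R1	11	C	0.62	-0.052	.	3.3e-20	18.78	1.05	1.02	1.09	3.9e-3	IMSGC_Immunochip	.	.	synthesis
rs12785878	DHCR7	11	G	0.27	-0.056	.	2.1e-27	18.29	1.11	1.07	1.15	8.7e-9	IMSGC_Immunochip	rs4944958	1.0	synthesis
rs2282679	GC	4	C	0.30	-0.047	.	1.9e-109	13.38	1.04	1.00	1.08	6.2e-2	IMSGC_WTCCC2	.	.	metabolism
rs6013897	CYP24A1	20	A	0.19	-0.027	.	6.0e-10	3.13	1.07	1.03	1.11	1.7e-3	IMSGC_WTCCC2	rs17217119	1.0	metabolism
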