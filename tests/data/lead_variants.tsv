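rsID	CHR	BP	EA	OA	BETA	SE	P	EAF	N	HetPval	Phenotype	Nearest_gene
rs10260148	7	130,430,969	C	T	−0.061	0.009	2.E‐12	0.72	28,402	7.E‐04	SAT fSFA	KLF14
rs59186169	7	155,050,209	A	G	−0.116	0.017	3.E‐11	0.95	28,402	4.E‐01	SAT fSFA	INSIG1
rs603424	10	102,075,479	G	A	−0.386	0.011	4.E‐293	0.83	28,402	9.E‐10	SAT fSFA	PKD2L1
rs660745	19	49,219,459	T	C	0.044	0.007	2.E‐08	0.46	28,402	1.E‐02	SAT fPUFA	MAMSTR
rs67261871	3	156,797,941	T	C	−0.051	0.008	1.E‐10	0.6	28,402	5.E‐05	SAT fSFA	LEKR1
rs73221948	8	25,464,670	G	T	0.06	0.009	4.E‐11	0.71	28,413	6.E‐06	VAT fMUFA	CDCA2
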