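chain_a	region_a	aa3_a	aa1_a	imgt_a	author_a	kind	distance	chain_b	region_b	aa3_b	aa1_b	imgt_b	author_b
G	CDR1	ASN	N	37		HBOND_SS		D	CDR3	ASP	D	111.9	
G	CDR1	TYR	Y	38		HBOND_SS		D	CDR3	ARG	R	111.7	
G	FR2	HIS	H	40		IONIC		D	CDR3	ASP	D	111.9	
G	FR2	HIS	H	40		HBOND_SS		D	CDR3	ARG	R	112	
G	FR2	TYR	Y	42		CATION_PI		D	CDR3	ARG	R	112	
G	FR2	TYR	Y	42		HBOND_SS		D	CDR3	ARG	R	112	
G	FR2	PHE	F	44		AROMATIC_AROMATIC		D	FR3	PHE	F	103	
G	FR2	ARG	R	52		CATION_PI		D	CDR3	TRP	W	111.10	
G	FR2	TYR	Y	55		CATION_PI		D	CDR3	ARG	R	111.7	
G	FR2	TYR	Y	55		HBOND_SS		D	CDR3	ARG	R	111.7	
G	CDR3	TYR	Y	111.1		AROMATIC_AROMATIC		D	FR2	PHE	F	52	
G	CDR3	SER	S	112		HBOND_SS		D	CDR3	TRP	W	112.6	
G	CDR3	TRP	W	114		CATION_PI		D	CDR3	ARG	R	111.4	
G	CDR3	ARG	R	115		CATION_PI		D	FR2	PHE	F	52	
G	CDR3	ARG	R	115		HBOND_SS		D	CDR3	ASP	D	107	
G	CDR3	LYS	K	116		IONIC		D	CDR3	ASP	D	107	
G	CDR3	LYS	K	116		HBOND_SS		D	CDR3	ASP	D	107	
G	CDR3	LYS	K	116		CATION_PI		D	CDR3	TYR	Y	111.2	
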