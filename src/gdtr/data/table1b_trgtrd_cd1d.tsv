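chain_a	region_a	aa3_a	aa1_a	imgt_a	author_a	kind	distance	chain_b	region_b	aa3_b	aa1_b	imgt_b	author_b
D	CDR1	TRP	W	29		AROMATIC_AROMATIC		C	G-ALPHA1-LIKE	PHE	F	55	
D	CDR3	ARG	R	111.7		IONIC		C	G-ALPHA1-LIKE	GLU	E	61	
D	CDR3	ARG	R	111.7		HBOND_SS		C	G-ALPHA1-LIKE	ASN	N	62	
D	CDR3	ASP	D	111.9		IONIC		C	G-ALPHA1-LIKE	HIS	H	65	
G	CDR1	TYR	Y	38		HBOND_SS		C	G-ALPHA1-LIKE	HIS	H	65	
G	CDR2	ASP	D	57		IONIC		C	G-ALPHA1-LIKE	HIS	H	65	
G	CDR2	LYS	K	64		IONIC		C	G-ALPHA1-LIKE	ASP	D	43	
D	CDR1	SER	S	30		HBOND_SS		C	G-ALPHA2-LIKE	SER	S	72A	
D	CDR3	ARG	R	109		CATION_PI		C	G-ALPHA2-LIKE	TRP	W	69	
D	CDR3	TRP	W	111.5		AROMATIC_AROMATIC		C	G-ALPHA2-LIKE	TRP	W	69	
D	FR2	ARG	R	55		IONIC		C	G-ALPHA2-LIKE	GLU	E	65	
D	CDR3	ARG	R	111.4		IONIC		C	G-ALPHA2-LIKE	GLU	E	65	
D	CDR3	ARG	R	111.4		HBOND_SS		C	G-ALPHA2-LIKE	GLU	E	65	
G	CDR3	TRP	W	114		HBOND_SS		C	G-ALPHA2-LIKE	GLU	E	65	
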