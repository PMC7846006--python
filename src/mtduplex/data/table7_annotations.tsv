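position	ref	alt	locus_type	locus	aa_change	codon_position	rs_id	pathogenicity_note
1120	C	T	rRNA	MT-RNR1			rs727505171	Progressive Encephalopathy / PEO, myopathy
1284	T	C	rRNA	MT-RNR1				
1556	C	T	rRNA	MT-RNR1				Sensorineural Hearing Loss
4104	A	G	Coding	MT-ND1	Syn:Leu266	3	rs1117205	
4556	C	T	Coding	MT-ND2	Syn:Thr29	3		PhyloP score -0.48 (Negative, fast-evolving site)
5320	C	T	Coding	MT-ND2	Thr284Ile	2		PhyloP score -3.21
5471	G	A	Coding	MT-ND2	Syn:Thr334	3		PhyloP score -10.63
5474	A	G	Coding	MT-ND2	Syn:Leu335	3		PhyloP score -12.09
5498	A	G	Coding	MT-ND2	Syn:Met343	3		PhyloP score 6.56 (Positive, conserved site)
5840	C	T	tRNA	MT-TY				HmtVar Prediction: Likely Polymorphic Disease score <0.35
6023	G	A	Coding	MT-CO1	Syn:Glu40	3		
7146	A	G	Coding	MT-CO1	Thr415Ala	1	rs372136420	HmtVar Prediction: Polymorphic Disease score <0.43
7256	C	T	Coding	MT-CO1	Syn:Asn451	3		
9075	C	T	Coding	MT-ATP6	Syn:Thr183	3		
9168	C	T	Coding	MT-ATP6	Syn:Phe214	3		
9254	A	G	Coding	MT-CO3	Syn:Trp16	3	rs386829072	Pancreatic cancer cell line
9629	A	G	Coding	MT-CO3	Syn:Gly141	3		
11914	G	A	Coding	MT-ND4	Syn:Thr385	3	rs2853496	
12705	C	T	Coding	MT-ND5	Syn:Ile123	3	rs193302956	Prostate tumor
13095	T	C	Coding	MT-ND5	Syn:Val253	3	rs28477492	
13105	A	G	Coding	MT-ND5	Ile257Val	1	rs2853501	HmtVar Prediction: Polymorphic Disease score < 0.42
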