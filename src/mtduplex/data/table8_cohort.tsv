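# groups: young_nl n=83, old_nl n=66, old_amd n=73
position	ref	alt	total_carriers	young_nl	old_nl	old_amd
1120	C	T	219	82	64	73
1284	T	C	218	82	64	72
1556	C	T	218	82	64	72
4104	A	G	187	82	50	55
4556	C	T	0	0	0	0
5320	C	T	185	78	51	56
5471	G	A	170	78	44	48
5474	A	G	170	78	44	48
5498	A	G	156	74	37	45
5840	C	T	194	77	54	63
6023	G	A	198	78	55	65
7146	A	G	197	78	56	63
7256	C	T	216	81	64	71
9075	C	T	198	78	55	65
9168	C	T	196	78	54	64
9254	A	G	192	78	51	63
9629	A	G	192	78	52	62
11914	G	A	188	75	51	62
12705	C	T	182	69	50	63
13095	T	C	165	56	47	62
13105	A	G	166	57	46	63
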