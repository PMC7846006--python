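position	ref	alt	s1_blood	s1_rpe_choroid	s1_retina	s2_blood	s2_rpe_choroid	s2_retina	s3_blood	s3_rpe_choroid	s3_retina
73	A	G	99.29	99.73	99.81				99.68	99.79	99.81
152	T	C							99.69	99.78	99.76
195	T	C							99.57	99.68	99.73
199	T	C	98.25	98.90	99.29						
203	G	A	98.51	99.16	99.54						
204	T	C	99.04	98.13	99.01						
217	T	C							99.53	98.25	97.01
263	A	G				99.81	99.82	99.82	99.77	99.75	99.80
508	A	G							99.70	99.70	99.79
1719	G	A	99.43	99.51	99.70						
1811	A	G							97.82	99.12	99.44
2706	A	G	99.68	99.79	99.84				99.77	99.76	99.78
3447	A	G	99.38	99.70	99.79						
3720	A	G							99.75	99.71	99.81
3849	G	A							99.70	99.73	99.73
3990	C	T	98.66	99.17	99.03						
4529	A	T	98.60	99.12	99.12						
4553	T	C							90.03	98.53	98.96
4736	T	C							99.81	99.74	99.81
4793	A	G				97.73	99.37	99.08			
5348	C	T				97.72	99.36	99.05			
5390	A	G							92.42	98.88	99.22
5426	T	C							99.68	99.74	99.77
6045	C	T							89.53	98.48	98.98
6152	T	C							89.66	98.62	98.83
6734	G	A	98.38	99.37	99.38						
7028	C	T	99.13	99.45	99.60				95.95	99.25	99.41
8251	G	A	98.38	99.29	99.26						
8473	T	C							90.96	98.73	99.18
9947	G	A	99.48	99.63	99.70						
10034	T	C	99.73	99.76	99.84						
10238	T	C	99.70	99.71	99.84						
10398	A	G	99.68	99.86	99.90						
10876	A	G							99.05	99.60	99.75
10915	T	C	99.73	99.75	99.82						
11467	A	G							98.78	99.66	99.75
11719	G	A	99.37	99.66	99.71				99.63	99.51	99.66
12308	A	G							99.74	99.77	99.81
12372	G	A							99.68	99.63	99.71
12501	G	A	97.98	99.16	99.16						
12557	C	T							89.93	98.32	98.91
12705	C	T	99.12	99.59	99.71						
13020	T	C							89.55	98.46	98.92
13734	T	C							99.75	99.70	99.80
13780	A	G	99.45	99.58	99.67						
14182	T	C	99.72	99.72	99.75						
14766	C	T	99.62	99.76	99.79				99.71	99.73	99.75
15043	G	A	99.40	99.60	99.67						
15907	A	G							99.76	99.78	99.81
15924	A	G	99.74	99.75	99.77						
16051	A	G							99.65	99.57	99.73
16129	G	A	99.13	95.51	92.08						
16129	G	C							99.56	99.58	99.58
16172	T	C	99.64	99.63	99.79						
16189	T	C							97.23	96.55	97.61
16223	C	T	99.28	99.45	99.66						
16311	T	C	99.64	99.35	99.70						
16362	T	C							99.54	99.60	99.70
16391	G	A	99.19	99.22	99.48						
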