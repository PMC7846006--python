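position	ref	alt	s1_blood	s1_rpe_choroid	s1_retina	s2_blood	s2_rpe_choroid	s2_retina	s3_blood	s3_rpe_choroid	s3_retina
64	C	T					1.21				
72	T	C					5.22	8.62			
76	C	T		3.60	1.80						
189	A	G								1.41	1.56
309	C	T	4.86	2.90	3.37	3.36	3.47	3.40			
310	T	C	10.75	8.91	8.60	8.80	9.13	9.02		3.55	
328	A	G	11.60	19.38	8.04						
567	A	C	3.36								
813	A	G							7.56		
825	T	A							7.50		
868	C	T	1.44								
1039	A	G							1.19		
1040	T	C							1.14		
1106	C	T				1.72			4.16		
1120	C	T	1.67			3.23		1.24	8.92	1.40	
1123	C	G							3.66		
1556	C	T	2.14			3.68		1.38	10.52	1.69	
1267	T	C				2.09			6.55		
1284	T	C	1.90			2.73		1.16	8.20		
1291	T	C				1.98			6.49		
1292	A	G	1.81			2.69			8.03		
1520	T	C				1.88			5.40		
1536	A	G				1.33			2.96		
1619	C	T	1.46			1.81			5.07		
1661	A	G				50.55	1.41				
1842	A	G	1.64						3.11		
1883	G	A							3.08		
1888	G	A				2.07			6.15		
1889	C	A							2.24		
1900	A	G							2.35		
1944	C	T							2.07		
1977	T	C				1.63			4.56		
1978	A	G							3.12		
2000	C	T				1.44			4.87		
2056	G	A				1.56			4.99		
2059	C	T				1.46			4.92		
2080	T	C							2.04		
2143	G	A	1.64			2.35			6.27		
2162	C	T	1.65			2.30			6.30		
2168	T	C							1.95		
2523	C	T	1.74	1.29	1.35	2.84		1.22	6.82		
2541	C	A				2.18			6.61		
2557	C	T				1.39			3.39		
2572	C	T				1.09			3.21		
4048	G	A				2.18			9.17	1.33	
4104	A	G	1.37			2.28			9.44	1.44	
4312	C	T				2.10			10.29		
4318	C	T				2.10			10.29		
4456	C	T				2.11			12.22	1.84	
4736	T	C				2.22					
4856	T	C				1.87			8.50		
4904	C	T							6.55		
4914	C	T							6.54		
4940	C	T				1.31			6.04		
4958	A	G							5.17		
4991	G	A							5.08		
5041	T	C				1.74			5.39		
5147	G	A				1.72			7.60		
5320	C	T				2.13			9.85	1.19	
5351	A	G				2.02			7.48		
5385	C	T							2.11		
5387	C	T				1.97			7.39		
5426	T	C				2.01					
5471	G	A				2.50			11.74	1.47	
5474	A	G				2.45			11.67	1.43	
5493	T	C				11.87					
5498	A	G				2.49			11.73	1.40	
5580	T	C				2.52			10.66		
5821	G	A				3.38			11.76	1.91	
5840	C	T	1.34			2.49			10.62	1.32	
6023	G	A	1.16			2.23			10.22	1.22	
6221	T	C				2.02			8.99		
6242	C	T				1.60			7.39		
6266	A	C				1.47			7.32		
6299	A	G				1.74			8.30		
6366	G	A	1.51			1.75			9.00		
6383	G	A				1.64			7.80		
6405	A	G				3.37					
6410	C	T				1.45			6.34		
6452	C	T				1.45			6.30		
6483	C	T				1.50			6.49		
6512	T	C				1.77			7.14		
6542	C	T				1.61			7.00		
6569	C	A				1.99			9.19		
6641	T	C				2.26			10.11	1.18	
6935	C	T				2.03			9.72		
6938	C	T				2.01			9.65		
7146	A	G	1.40			2.71			11.46	1.37	
7195	T	C							3.26		
7197	G	A				2.53					
7216	G	A							3.42		
7232	C	T				2.09			8.77		
7256	C	T			1.26	3.78		1.40	13.51	1.70	
7286	T	C				2.48			6.77		
7299	A	G							4.98		
7316	G	A				1.53			6.96		
7325	A	G							5.00		
7337	G	A				2.38			6.70		
7364	A	G							5.14		
7473	A	G							4.44		
7521	G	A				2.08			13.21	1.56	
7559	A	G							3.59		
7571	A	G				1.53					
7610	C	T							3.03		
7650	C	T				1.92			12.74	1.39	
7702	G	A	1.55								
7705	T	C				2.15			13.30	1.58	
7757	G	A				2.07			3.46		
7810	C	T				1.75			11.54		
7861	T	C							1.81		
7868	C	T				1.67			9.46		
7891	C	T				1.69			7.56		
7912	G	A				1.70			7.65		
8021	A	G	1.28			2.13			7.48		
8065	G	A	1.19			2.29			9.77		
8167	T	C							3.98		
8203	C	T				2.06			9.85		
8392	G	A				1.73			11.20		
8455	C	T				1.64			10.07		
8461	C	T				1.64			10.02		
8503	T	C				1.72			9.10		
8537	A	G				6.70					
8545	G	A				2.02			9.94		
8655	C	T				1.88			8.54		
8677	A	C				1.52			7.01		
8701	A	G	1.52			1.70			7.13		
8718	A	G	1.32			1.82			7.19		
8943	C	T				2.04			10.20		
9060	C	A				2.16			10.07		
9075	C	T	1.41			2.29			10.68	1.30	
9168	C	T	1.45			2.25			10.33	1.26	
9254	A	G	1.33			2.44			9.71	1.28	
9325	T	C				2.30			10.71		
9329	G	C				2.17			10.72		
9434	A	G				2.19			10.34	1.31	
9629	A	G	2.41			2.13			9.55	1.39	
10945	A	G	1.58						1.52		
10978	A	G							1.46		
11016	G	A							1.45		
11083	A	G				1.98			6.30		
11097	C	T				1.94			6.29		
11147	T	C				1.79			4.82		
11176	G	A				1.43			3.16		
11197	C	T				1.40			3.16		
11233	T	C							1.65		
11527	C	T				2.06			6.65		
11557	A	G				2.15			6.67		
11590	A	G				2.02			6.73		
11662	T	C				2.07			6.85		
11852	G	A							3.14		
11857	C	T							3.00		
11887	G	A				1.76			5.42		
11914	G	A	1.89	1.43	1.47	1.80			5.43		
11963	G	A				1.65			5.75		
12007	G	A				1.67			5.85		
12013	A	G				1.76			5.87		
12018	C	G							3.75		
12561	G	A							3.71		
12684	G	A				2.26			10.52	1.60	
12705	C	T				2.26			10.51	1.63	
13062	A	G				2.21			10.83	1.59	
13095	T	C	1.96			2.38			9.43	1.64	
13105	A	G	1.80			2.32			9.41	1.55	
13242	A	G				1.51			2.29		
13260	T	C				1.59			2.36		
13272	C	T				1.30			2.00		
13281	T	C				1.36			2.08		
13359	G	A							3.54		
13368	G	A							3.51		
13386	T	C	1.28			1.78			5.13		
13440	C	T				1.61			4.89		
13466	G	A				1.55			4.70		
13476	A	G				1.55			4.65		
13488	T	C				1.76			4.99		
13563	A	G							6.73		
13581	T	C							6.73		
14149	C	T							3.11		
14170	A	T							3.15		
14172	T	G				1.58			4.74		
14182	T	C				1.74			4.90		
14950	C	T							3.74		
14956	T	C				1.21			3.85		
14969	T	C							3.72		
15191	T	C	1.84	1.50	1.69						
15301	G	A	2.80	1.92	2.19						
16129	G	A				9.25					
16182	A	C							26.73	24.66	23.82
16183	A	C							60.43	58.92	60.06
16444	C	T				1.42					
16496	G	A				1.50					
16527	C	T				2.08					
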