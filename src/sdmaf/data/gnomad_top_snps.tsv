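Region	SNP	Population	Sex	Call rate	RR	RA	AA	Minor Allele
PAR1	X-2779827-G-A	NFE	F	99.72	19436	194	1	A
PAR1	X-2779827-G-A	NFE	M	99.50	626	13577	67	A
PAR1	X-2779827-G-A	AFR	F	99.16	6772	3707	514	A
PAR1	X-2779827-G-A	AFR	M	99.08	248	7346	1975	A
PAR1	X-2780882-G-A	NFE	F	99.85	19567	89	0	A
PAR1	X-2780882-G-A	NFE	M	99.64	91	14150	39	A
PAR1	X-2780882-G-A	AFR	F	99.51	8781	2118	133	A
PAR1	X-2780882-G-A	AFR	M	99.64	137	8442	1044	A
NPR	X-52861869-T-C	NFE	F	98.54	14176	5222	1	C
NPR	X-52861869-T-C	NFE	M	85.50	12189	NA	73	C
NPR	X-52861869-T-C	AFR	F	99.36	9642	1368	5	C
NPR	X-52861869-T-C	AFR	M	90.36	8552	NA	175	C
PAR3	X-89688092-A-G	NFE	F	99.48	13994	5106	483	G
PAR3	X-89688092-A-G	NFE	M	89.78	11538	NA	1338	G
PAR3	X-89688092-A-G	AFR	F	99.56	9694	1300	43	G
PAR3	X-89688092-A-G	AFR	M	84.52	7865	NA	298	G
PAR3	X-90958827-T-C	NFE	F	99.38	15016	4218	330	C
PAR3	X-90958827-T-C	NFE	M	91.08	12039	NA	1025	C
PAR3	X-90958827-T-C	AFR	F	99.31	9611	1353	45	C
PAR3	X-90958827-T-C	AFR	M	85.60	7990	NA	277	C
NPR	X-141051591-A-G	NFE	F	99.31	14846	4700	5	G
NPR	X-141051591-A-G	NFE	M	79.08	11253	NA	89	G
NPR	X-141051591-A-G	AFR	F	98.57	8826	2095	7	G
NPR	X-141051591-A-G	AFR	M	84.68	8057	NA	121	G
PAR2	X-155706522-G-A	NFE	F	98.23	19321	16	0	A
PAR2	X-155706522-G-A	NFE	M	97.92	30	14012	2	A
PAR2	X-155706522-G-A	AFR	F	98.71	10933	10	0	A
PAR2	X-155706522-G-A	AFR	M	99.26	11	9573	3	A
PAR2	X-155712209-T-G	NFE	F	99.63	19585	28	0	G
PAR2	X-155712209-T-G	NFE	M	99.12	29	14186	2	G
PAR2	X-155712209-T-G	AFR	F	99.58	10520	516	3	G
PAR2	X-155712209-T-G	AFR	M	99.78	14	9404	218	G
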