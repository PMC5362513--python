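sample_id	locus_id	allele	fwd_count	rev_count	mean_base_quality	mean_mapq
JHU Pt 1	L702H	T	6445	6444	33.0	60.0
JHU Pt 1	W742C	G	1164	1163	33.0	60.0
JHU Pt 1	H875Y	C	2286	2286	33.0	60.0
JHU Pt 1	F877L	T	2600	2599	33.0	60.0
JHU Pt 1	T878A	A	2527	2526	33.0	60.0
JHU Pt 2	L702H	T	6994	6993	33.0	60.0
JHU Pt 2	W742C	G	1927	1926	33.0	60.0
JHU Pt 2	H875Y	C	3031	3030	33.0	60.0
JHU Pt 2	F877L	T	3692	3692	33.0	60.0
JHU Pt 2	T878A	A	3579	3579	33.0	60.0
JHU Pt 3	L702H	T	11792	11791	33.0	60.0
JHU Pt 3	W742C	G	2260	2259	33.0	60.0
JHU Pt 3	W742C	T	11	10	33.0	60.0
JHU Pt 3	H875Y	C	5010	5009	33.0	60.0
JHU Pt 3	F877L	T	5576	5576	33.0	60.0
JHU Pt 3	F877L	C	13	13	33.0	60.0
JHU Pt 3	T878A	A	5414	5414	33.0	60.0
JHU Pt 4	L702H	T	8187	8187	33.0	60.0
JHU Pt 4	W742C	G	1934	1933	33.0	60.0
JHU Pt 4	H875Y	C	3492	3491	33.0	60.0
JHU Pt 4	F877L	T	4108	4107	33.0	60.0
JHU Pt 4	T878A	A	3962	3962	33.0	60.0
JHU Pt 4	T878A	G	17	16	33.0	60.0
JHU Pt 5	L702H	T	13336	13336	33.0	60.0
JHU Pt 5	W742C	G	2537	2536	33.0	60.0
JHU Pt 5	H875Y	C	2802	2801	33.0	60.0
JHU Pt 5	F877L	T	3409	3409	33.0	60.0
JHU Pt 5	T878A	A	3300	3300	33.0	60.0
JHU Pt 6	L702H	T	220481	220481	33.0	60.0
JHU Pt 6	W742C	G	54035	54034	33.0	60.0
JHU Pt 6	H875Y	C	118148	118148	33.0	60.0
JHU Pt 6	F877L	T	141934	141933	33.0	60.0
JHU Pt 6	T878A	A	137209	137209	33.0	60.0
JHU Pt 7	L702H	T	12751	12750	33.0	60.0
JHU Pt 7	W742C	G	3555	3554	33.0	60.0
JHU Pt 7	H875Y	C	5541	5541	33.0	60.0
JHU Pt 7	F877L	T	6693	6693	33.0	60.0
JHU Pt 7	F877L	C	18	18	33.0	60.0
JHU Pt 7	T878A	A	6497	6497	33.0	60.0
JHU Pt 8	L702H	T	10572	10571	33.0	60.0
JHU Pt 8	W742C	G	2356	2355	33.0	60.0
JHU Pt 8	H875Y	C	3916	3916	33.0	60.0
JHU Pt 8	F877L	T	4432	4431	33.0	60.0
JHU Pt 8	F877L	C	13	12	33.0	60.0
JHU Pt 8	T878A	A	4278	4277	33.0	60.0
JHU Pt 9	L702H	T	8565	8564	33.0	60.0
JHU Pt 9	W742C	G	2265	2264	33.0	60.0
JHU Pt 9	H875Y	C	3659	3658	33.0	60.0
JHU Pt 9	F877L	T	4528	4527	33.0	60.0
JHU Pt 9	T878A	A	4396	4396	33.0	60.0
JHU Pt 10	L702H	T	25846	25845	33.0	60.0
JHU Pt 10	W742C	G	5694	5694	33.0	60.0
JHU Pt 10	H875Y	C	8748	8747	33.0	60.0
JHU Pt 10	F877L	T	10161	10161	33.0	60.0
JHU Pt 10	F877L	C	26	25	33.0	60.0
JHU Pt 10	T878A	A	9803	9803	33.0	60.0
JHU Pt 11	L702H	T	9633	9632	33.0	60.0
JHU Pt 11	W742C	G	1570	1570	33.0	60.0
JHU Pt 11	H875Y	C	3311	3310	33.0	60.0
JHU Pt 11	F877L	T	3667	3667	33.0	60.0
JHU Pt 11	F877L	C	8	7	33.0	60.0
JHU Pt 11	T878A	A	3567	3567	33.0	60.0
Male Control	L702H	T	10946	10945	33.0	60.0
Male Control	W742C	G	3265	3264	33.0	60.0
Male Control	H875Y	C	8228	8227	33.0	60.0
Male Control	F877L	T	8805	8804	33.0	60.0
Male Control	F877L	C	15	15	33.0	60.0
Male Control	T878A	A	9280	9280	33.0	60.0
Female Control	L702H	T	18567	18567	33.0	60.0
Female Control	W742C	G	4957	4956	33.0	60.0
Female Control	H875Y	C	16621	16621	33.0	60.0
Female Control	F877L	T	17721	17720	33.0	60.0
Female Control	T878A	A	17640	17639	33.0	60.0
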