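table	sample_id	sample_type	locus_id	polymerase	cycles	preamplified	mut_droplets	wt_droplets	percent_mutant_printed
T4	JHU Pt 1	patient	F877L	Phusion	22	1	5	18298	0.027
T4	JHU Pt 2	patient	F877L	Phusion	22	1	8	31108	0.026
T4	JHU Pt 3	patient	F877L	Phusion	22	1	5	27672	0.018
T4	JHU Pt 4	patient	F877L	Phusion	22	1	5	35181	0.014
T4	JHU Pt 5	patient	F877L	Phusion	22	1	11	32975	0.033
T4	JHU Pt 6	patient	F877L	Phusion	22	1	0	41833	0.0
T4	JHU Pt 7	patient	F877L	Phusion	22	1	7	68073	0.01
T4	JHU Pt 8	patient	F877L	Phusion	22	1	10	36587	0.027
T4	JHU Pt 9	patient	F877L	Phusion	22	1	6	25642	0.023
T4	JHU Pt 10	patient	F877L	Phusion	22	1	4	59673	0.007
T4	JHU Pt 11	patient	F877L	Phusion	22	1	8	37478	0.021
T4	Wild-type Genomic DNA	wt_control	F877L	Phusion	22	1	11	30348	0.036
T4	No Template Control	ntc	F877L	Phusion	22	1	0	0	0.0
T4	Wild-type Genomic DNA	wt_control	F877L	Phusion	0	0	0	36018	0.0
T4	F877L Mutant Control	mutant_control	F877L	Phusion	0	0	964	0	100
T4	No Template Control	ntc	F877L	Phusion	0	0	0	0	0.0
T4	JHU Pt 3	patient	F877L	SuperFi	22	1	0	14824	0.0
T4	JHU Pt 4	patient	F877L	SuperFi	22	1	0	14164	0.0
T4	JHU Pt 7	patient	F877L	SuperFi	22	1	0	40588	0.0
T4	JHU Pt 8	patient	F877L	SuperFi	22	1	0	10163	0.0
T4	JHU Pt 10	patient	F877L	SuperFi	22	1	0	16317	0.0
T4	JHU Pt 11	patient	F877L	SuperFi	22	1	0	17926	0.0
T4	Wild-type Genomic DNA	wt_control	F877L	SuperFi	22	1	0	44104	0.0
T4	No Template Control	ntc	F877L	SuperFi	22	1	0	0	0.0
T4	Wild-type Genomic DNA	wt_control	F877L	SuperFi	0	0	0	7761	0.0
T4	F877L Mutant Control	mutant_control	F877L	SuperFi	0	0	810	0	100
T4	No Template Control	ntc	F877L	SuperFi	0	0	0	0	0.0
T5	JHU Pt 1	patient	T878A	Phusion	22	1	1	11707	0.009
T5	JHU Pt 3	patient	T878A	Phusion	22	1	1	15126	0.007
T5	JHU Pt 4	patient	T878A	Phusion	22	1	3	26983	0.011
T5	JHU Pt 7	patient	T878A	Phusion	22	1	0	12156	0.0
T5	JHU Pt 8	patient	T878A	Phusion	22	1	1	24205	0.004
T5	JHU Pt 10	patient	T878A	Phusion	22	1	0	51299	0.0
T5	JHU Pt 11	patient	T878A	Phusion	22	1	1	27082	0.004
T5	Wild-type Genomic DNA	wt_control	T878A	Phusion	22	1	2	36329	0.006
T5	No Template Control	ntc	T878A	Phusion	22	1	0	0	0.0
T5	Wild-type Genomic DNA	wt_control	T878A	Phusion	0	0	0	16132	0.0
T5	T878A Mutant Control	mutant_control	T878A	Phusion	0	0	122	0	100
T5	No Template Control	ntc	T878A	Phusion	0	0	0	0	0.0
T5	JHU Pt 1	patient	T878A	SuperFi	22	1	0	41931	0.0
T5	JHU Pt 3	patient	T878A	SuperFi	22	1	0	26745	0.0
T5	JHU Pt 4	patient	T878A	SuperFi	22	1	0	30737	0.0
T5	JHU Pt 7	patient	T878A	SuperFi	22	1	0	35931	0.0
T5	JHU Pt 8	patient	T878A	SuperFi	22	1	0	27729	0.0
T5	JHU Pt 10	patient	T878A	SuperFi	22	1	0	20279	0.0
T5	JHU Pt 11	patient	T878A	SuperFi	22	1	0	32648	0.0
T5	Wild-type Genomic DNA	wt_control	T878A	SuperFi	22	1	0	21511	0.0
T5	No Template Control	ntc	T878A	SuperFi	22	1	0	0	0.0
T5	T878A Positive cfDNA	positive_cfdna	T878A	SuperFi	22	1	233	11890	1.96
T5	Wild-type Genomic DNA	wt_control	T878A	SuperFi	0	0	0	24915	0.0
T5	T878A Mutant Control	mutant_control	T878A	SuperFi	0	0	7502	0	100
T5	No Template Control	ntc	T878A	SuperFi	0	0	0	0	0.0
T6	Wild-type Genomic DNA	wt_control	F877L	Phusion	22	1	11	30348	0.036
T6	Wild-type Genomic DNA	wt_control	F877L	Phusion	12	1	1	8539	0.012
T6	Wild-type Genomic DNA	wt_control	F877L	SuperFi	22	1	0	44104	0.0
T6	Wild-type Genomic DNA	wt_control	T878A	Phusion	22	1	2	36329	0.006
T6	Wild-type Genomic DNA	wt_control	T878A	Phusion	12	1	1	9617	0.01
T6	Wild-type Genomic DNA	wt_control	T878A	SuperFi	22	1	0	21511	0.0
T7	JHU Pt 3	patient	W742C	Phusion	22	1	4	25067	0.016
T7	JHU Pt 7	patient	W742C	Phusion	22	1	0	19753	0.0
T7	Wild-type Genomic DNA	wt_control	W742C	Phusion	22	1	0	17573	0.0
T7	No Template Control	ntc	W742C	Phusion	22	1	0	0	0.0
T7	Wild-type Genomic DNA	wt_control	W742C	Phusion	0	0	0	31225	0.0
T7	W742C Mutant Control	mutant_control	W742C	Phusion	0	0	10602	0	100
T7	No Template Control	ntc	W742C	Phusion	0	0	0	0	0.0
T7	JHU Pt 3	patient	W742C	SuperFi	22	1	38	33611	0.113
T7	JHU Pt 7	patient	W742C	SuperFi	22	1	0	15958	0.0
T7	Wild-type Genomic DNA	wt_control	W742C	SuperFi	22	1	0	37069	0.0
T7	No Template Control	ntc	W742C	SuperFi	22	1	0	0	0.0
T7	Wild-type Genomic DNA	wt_control	W742C	SuperFi	0	0	0	31225	0.0
T7	W742C Mutant Control	mutant_control	W742C	SuperFi	0	0	10602	0	100
T7	No Template Control	ntc	W742C	SuperFi	0	0	0	0	0.0
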