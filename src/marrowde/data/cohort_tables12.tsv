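subject_id	sampling_day	age_at_hsct	conditioning	all_risk	donor_source	hla_match	prophylaxis	agvhd	agvhd_grade	cgvhd	relapse	batch
P01	100	19	Flu/Tre/Thiotepa	high	unrelated	10/10	Tacro/MMF	1	3	1	0	b1
P02	100	9	TBI/Cy	high	related	5/10	Tacro/MMF/PTCy	1	3	1	1	b1
P03	100	16	Flu/TBI/Cy	high	related	5/10	Tacro/MMF/PTCy	1	1	0	1	b1
P04	100	18	Thiotepa/TBI/Cy	high	related	9/10	Tacro/MMF	1	2	0	1	b1
P05	100	5	Etoposide/TBI/Cy	high	related	10/10	CsA/MMF	1	1	0	0	b1
P06	100	7	TBI/Cy	standard	related	10/10	Tacro/MMF	0	0	0	1	b2
P07	60	8	TBI/Cy	standard	related	5/10	Tacro/MMF/PTCy	0	0	1	0	b2
P08	60	12	TBI/Cy	standard	related	5/10	Tacro/MMF/PTCy	1	2	1	0	b2
P09	100	17	Thiotepa/TBI/Cy	high	unrelated	10/10	Tacro/Mtx	0	0	1	0	b2
P10	100	13	TBI/Cy	standard	unrelated	10/10	Tacro/MMF	1	3	1	0	b2
P11	100	7	TBI/Cy	high	related	10/10	Mtx	1	3	0	1	b3
P12	100	20	TBI/Cy	high	related	5/10	Tacro/MMF	1	1	0	0	b3
P13	100	15	TBI/Cy	high	related	5/10	Tacro/MMF/PTCy	1	3	0	0	b3
P14	100	3	TBI/Cy	standard	related	5/10	Tacro/MMF/PTCy	1	1	0	0	b3
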