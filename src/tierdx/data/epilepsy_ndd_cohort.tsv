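patient_id	diagnostic_level	sex	age_years	age_at_diagnosis_years	gene	genotype_class	phenotype_label
#1	1	M	17	15	GRIN2B	Het	DEE; Rett-like phenotype
#2	1	F	41	40	IQSEC2	Het	DEE; severe ID
#3	1	F	7	4	MECP2	Het	DEE; Rett Syndrome
#4	1	F	20	19	GNAO1	Het	DEE; profound ID
#5	1	M	32	29	CHD2	Het	FE; severe ID, ASD
#6	1	F	13	12	PURA	Het	DEE; profound ID
#7	1	M	6	5	KCNQ2	Het	GE; profound ID
#8	1	M	13	9	KCNQ2	Het	GE; profound ID, ASD
#9	1	F	14	12	IQSEC2	Het	FE; ID
#10	1	M	4	0.5	CDKL5	Hemi	DEE; Rett-like phenotype
#11	1	M	5	1	CDKL5	Hemi	DEE; Rett-like phenotype
#12	1	F	29	28	SLC2A1	Het	FE; moderate ID
#13	1	M	32	28	ADSL	Hom	DEE; profound ID
#14	1	M	7	4	SCN1A	Het	DEE (DS); psychomotor delay
#15	1	F	9	6	KCNT1	Het	FE; moderate ID
#16	1	F	7	3	SCN8A	Het	FE; moderate ID, autistic-like features
#17	1	F	12	9	SLC2A1	Het	GE; mild ID
#18	1	M	8	7	GRIN2A	Het	DEE (LKS); moderate ID
#19	1	M	17	16	IQSEC2	Hemi	GE; moderate ID
#20	1	M	6	3	GABRB3	Het	GE; psychomotor delay
#21	1	F	7	6	SLC6A1	Het	GE; mild ID
#22	2	F	21	20	DYNC1H1	Het	GE; mild ID
#23	2	F	11	10	PIGN	Hom	DEE; profound ID
#24	2	F	4	3	PIGN	Het	DEE; profound ID
#25	2	F	22	21	GNB1	Het	DEE; profound ID
#26	3	M	16	15	PRRT2	Het	FE; mild ID
#27	3	F	6	5	PIGC	Hom	DEE; profound ID
U01	0						
U02	0						
U03	0						
U04	0						
U05	0						
U06	0						
U07	0						
U08	0						
U09	0						
U10	0						
U11	0						
U12	0						
U13	0						
U14	0						
U15	0						
U16	0						
U17	0						
U18	0						
U19	0						
U20	0						
U21	0						
U22	0						
U23	0						
U24	0						
U25	0						
U26	0						
U27	0						
U28	0						
U29	0						
U30	0						
U31	0						
U32	0						
U33	0						
U34	0						
U35	0						
U36	0						
U37	0						
U38	0						
U39	0						
U40	0						
U41	0						
U42	0						
U43	0						
U44	0						
U45	0						
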