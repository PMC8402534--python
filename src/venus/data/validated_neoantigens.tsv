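tumor_type	patient_id	total_candidates	neoantigen_label	position	pct_better
Melanoma	3998	268	MAGEA6_E168K	1	0
Melanoma	3998	268	PDS5A_H1007Y	3	1
Melanoma	3998	268	MED13_P1691S	13	5
Melanoma	3784	494	FLNA_R2049C	5	1
Melanoma	3784	494	SON_R1927C	36	7
Melanoma	3784	494	KIF16B_L1009P	110	22
Melanoma	3903	435	KIF1BP_P246S	8	2
Rectal	3942	396	GPD2_E426K	19	5
Rectal	3942	396	NUP98_A359D	21	5
Rectal	3942	396	KARS_D328H	58	15
Colon	3995	138	RNF213_N1702S	13	9
Colon	3995	138	TUBGCP2_P265L	20	14
Colon	3995	138	KRAS_G12D	28	20
Colon	4007	262	SKIV2L_R653H	1	0
Colon	4032	136	API5_R243Q	2	1
Colon	4032	136	PHLPP1_G566E	4	3
Colon	4032	136	RNF10_E572K	16	12
Colon	4166	180	NPLOC_G1473V	1	0
Colon	4166	180	SUN1_A127T	9	5
Pancreas	4069	371	ZFYVE27_R6H	41	11
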