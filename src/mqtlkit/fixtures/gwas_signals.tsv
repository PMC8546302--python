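# Significant GWAS SNPs co-located with MQTL physical intervals.
# AX_109881378 was published with a position range 20.5-22.0 Mb; the midpoint
# 21.25 Mb is stored here (any point of the range lies inside MQTL_3B_1).
snp	chromosome	mb	trait	study	mqtl
AX_109881378	3B	21.25	GY	Li2019	MQTL_3B_1
M8680	4A	157.56	GY	Mathew2019	MQTL_4A_2
AX-110458478	5A	692.17	GY	Hu2020	MQTL_5A_4
AX-108839508	5A	692.16	GY	Hu2020	MQTL_5A_4
AX-109388349	5A	692.18	GY	Hu2020	MQTL_5A_4
AX-108829895	5A	692.39	GY	Hu2020	MQTL_5A_4
S7B_687521301	7B	687.52	NG	Jamil2019	MQTL_7B_2
AX-95235641	4D	442.17	PH	Hu2020	MQTL_4D_1
AX-110149206	7B	676.25	PH	Hu2020	MQTL_7B_2
AX-95658823	7B	675.28	PH	Hu2020	MQTL_7B_2
AX-95149761	7B	680.08	PH	Hu2020	MQTL_7B_2
AX-109901032	1B	566.19	SL	LiQ2019	MQTL_1B_2
AX-109394807	7A	29.32	SL	Hu2020	MQTL_7A_3
AX-109066809	4A	179.94	SN	LiQ2019	MQTL_4A_2
AX-111551006	2B	706.93	SNS	LiQ2019	MQTL_2B_1
AX-169338181	4D	433.00	SNS	LiQ2019	MQTL_4D_1
AX-111020167	4D	471.23	SNS	LiQ2019	MQTL_4D_1
AX-111542213	7A	4.55	SNS	LiQ2019	MQTL_7A_1
S4A_733664972	4A	733.66	TKW	Jamil2019	MQTL_4A_4
AX-111600193	4A	642.37	TKW	LiQ2019	MQTL_4A_3
AX-94402252	4B	564.39	TKW	Hu2020	MQTL_4B_3
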