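# Physical (Mb) anchoring of the most stable MQTLs on the wheat genome,
# with member-QTL counts and annotated gene counts per interval.
mqtl	chromosome	start_mb	end_mb	n_qtl	n_genes
MQTL_1A_4	1A	508.04	511.15	8	48
MQTL_1B_1	1B	16.23	27.30	7	170
MQTL_1B_2	1B	564.78	571.06	9	53
MQTL_1B_3	1B	678.45	681.00	7	30
MQTL_2A_1	2A	77.88	91.56	10	160
MQTL_2A_2	2A	38.75	56.93	12	189
MQTL_2A_3	2A	504.28	507.77	11	23
MQTL_2B_1	2B	686.82	707.65	8	223
MQTL_2B_2	2B	760.14	762.08	7	28
MQTL_3B_1	3B	16.67	50.54	18	457
MQTL_3B_2	3B	784.63	788.79	11	58
MQTL_3B_4	3B	822.58	830.11	6	112
MQTL_3B_5	3B	814.18	826.25	7	221
MQTL_3D_3	3D	31.87	38.29	7	63
MQTL_3D_4	3D	16.88	30.37	6	250
MQTL_4A_1	4A	474.79	488.25	7	66
MQTL_4A_2	4A	151.24	182.24	11	116
MQTL_4A_3	4A	632.62	656.77	9	204
MQTL_4A_4	4A	732.61	734.94	10	59
MQTL_4B_1	4B	601.95	640.98	7	348
MQTL_4B_2	4B	644.87	652.88	7	113
MQTL_4B_3	4B	509.04	576.50	9	479
MQTL_4B_4	4B	597.03	608.25	9	105
MQTL_4D_1	4D	425.23	490.12	6	802
MQTL_5A_3	5A	439.58	444.92	8	46
MQTL_5A_4	5A	671.39	702.96	10	427
MQTL_5D_2	5D	28.96	34.08	11	38
MQTL_7A_1	7A	1.47	4.99	16	86
MQTL_7A_2	7A	49.58	53.07	18	30
MQTL_7A_3	7A	25.06	41.48	18	233
MQTL_7A_4	7A	560.02	563.50	6	35
MQTL_7B_1	7B	32.55	36.92	9	55
MQTL_7B_2	7B	669.71	693.34	17	241
MQTL_7B_3	7B	557.05	582.70	14	170
MQTL_7B_4	7B	38.87	41.30	9	20
MQTL_7B_5	7B	741.47	744.92	8	107
MQTL_7B_6	7B	729.40	740.72	6	93
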