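# Published wheat MQTL catalog: 100 consensus loci with flanking markers,
# consensus-map position, 95% CI width (cM) and member trait codes.
name	chromosome	left_marker	right_marker	position_cM	ci_cM	traits
MQTL_1A_1	1A	BE470613.3	cwem0012	74.13	3.6	GWe
MQTL_1A_2	1A	barc176	wPt-7726	83.88	2.9	SNS
MQTL_1A_3	1A	barc0350	cfa2226	105.4	1	GY;SD;SL;SNS;TKW
MQTL_1A_4	1A	Xcfe257.2	Xpsp3151	113.51	2.1	DA;GY;NG;SD;SL;SW;TKW
MQTL_1A_5	1A	wPt-2855	wPt-663949	169.72	8.6	GMnC;SL
MQTL_1B_1	1B	gwm608	barc0008	15.34	4.31	DA;DPM;GFD;HW;SD;SDS;TKW
MQTL_1B_2	1B	barc8	wPt-0705	27.06	2.98	BDT;DA;DPM;GFD;GPC;HW;SDS;SL;TKW
MQTL_1B_3	1B	wmc813	LTR6150/ISSR3.380	35.00	2.75	BDT;GFD;GY;HW;NG;SDS;TKW
MQTL_1B_4	1B	barc80	wmc728	48.11	3.2	BDT;DDT;DST;FWA
MQTL_1B_5	1B	gwm140	aac/gac-10	53.01	3.19	DDT;DST;FWA;GY
MQTL_1B_6	1B	agt/ctg-1	act/gcg-2	61.31	2.49	DDT;DST;FWA;LS;SW
MQTL_1B_7	1B	act/cagt-1	ctcg/gtg-8	66.96	2.39	DDT;DST;FWA;MDR
MQTL_1B_8	1B	aag/cag-4	acc/cag-5	82.21	0.42	DDT;DST;FWA;NG;SL
MQTL_1D_1	1D	gwm147	Xcfe78.1	19.18	9.09	GFD;GPC;SDS;SNS
MQTL_1D_2	1D	Xbarc62.1	Xcwm70.2	34.03	2.94	DPM;GPC;SDS;TKW
MQTL_1D_3	1D	Xbarc240y	gwm0642	40.35	6.75	CDMA;DPM;GPC;PDMA;SDS
MQTL_1D_4	1D	Xcwm63.1	ww127.1	50.36	4.12	NG;PDMA
MQTL_1D_5	1D	Xcfd27.2	gwm337	59.23	2.18	CDMA;PDMA;TKW
MQTL_2A_1	2A	Xgwm382.1	wmc382	22.80	1.4	50%G;75%G;GFeC;GPC;GY;GZnC;MRS;SNS;TKW;TMRS
MQTL_2A_2	2A	wmc149	gwm497.1	36.87	3.35	50%G;75%G;GCuC;GFeC;GMnC;GPC;GWs;GY;MRS;NG;SNS;TMRS
MQTL_2A_3	2A	XPsr666	gdm101	54.37	3.09	25%G;50%G;75%G;DDT;DTF;GFD;GWs;GY;MRS;NG;TKW
MQTL_2A_4	2A	barc5	wPt-3114	68.17	6.85	BY;GFD;GY;MRS;NG
MQTL_2A_5	2A	Xswes940.2	aca/cta-11	93.68	3.15	GFR;GPC;LDMA;TKW
MQTL_2A_6	2A	wmc612	gwm4c	118.53	4.94	GFR;SN;TKW
MQTL_2A_7	2A	gwm311	wPt-799664	146.19	3	GMnC;NG
MQTL_2A_8	2A	Xbarc122	gwm122	170.28	0.39	GFR;GWs;GY;NG;KW
MQTL_2B_1	2B	cfd188	barc13	48.48	0.42	GFD;GY;KL;KW;NG;PH;SNS;TKW
MQTL_2B_2	2B	gwm114	Xmag3478	54.01	2.68	GY;KL;KW;NG;SN;SNS;TKW
MQTL_2B_3	2B	Xwmc617.1	Xmag3798	79.57	4.22	GPC;HI;SNS;TKW
MQTL_2B_4	2B	Xbarc160	Xwmc344.4	133.37	1.29	GY;NG
MQTL_2D_1	2D	wms102	gwm515	60.77	3.82	PH;SL;SW
MQTL_2D_2	2D	cfd233	aca/cta-2	74.48	1.97	NG;LY;PH
MQTL_2D_3	2D	agc/gcg-3.5	wmc445	85.6	3.58	PH
MQTL_3A_1	3A	Xbarc310	Xbarc321	1.00	3	LDMA
MQTL_3A_2	3A	Xwmc264	Xbarc1165	111.77	7	DA;PGMS;SNS
MQTL_3B_1	3B	wmc754	wPt-1191	81.11	1.99	BM;CID;DA;DTF;GN;GPC;GY;HI;LY;NG;PH;SL;SN;SNS;SW;TKW;TN
MQTL_3B_2	3B	wPt-664724	P39/M31-2	92.92	2.65	GY;HI;LY;NG;PH;SL;SN;SNS;TKW;TN
MQTL_3B_3	3B	P39/M50-2	cfb3059	109.1	2.07	75%G;SNS;TKW
MQTL_3B_4	3B	barc176	wmc632	114.03	2.38	75%G;GY;NG;SNS;TKW;TMRS
MQTL_3B_5	3B	cgt/ctcg-146	wPt-666764	119.72	0.38	75%G;DH;GY;SL;SNS;TKW;TMRS
MQTL_3D_1	3D	cfd223	wPt-743340	32.58	9.44	GZnC;SN;TKW
MQTL_3D_2	3D	Xgwm892	wPt-8914	66.11	14.3	PH
MQTL_3D_3	3D	wPt-733972	wPt-666681	121.94	3.88	BM;GCuC;GFeC;GPC;GY;HI;PH
MQTL_3D_4	3D	wPt-664771	wPt-742685	140.91	13.53	BM;GFeC;GPC;GY;HI;PH
MQTL_3D_5	3D	wPt-741976	wPt-740544	218.00	9.27	GSeC;GZnC
MQTL_4A_1	4A	wPt-664971	BE399880	54.58	1.71	GL;GPC;GPL;GY;GZnC;NG;SNS
MQTL_4A_2	4A	tgc/agc-166	cfd30	73.07	1.94	DH;GL;GPL;GY;GZnC;HW;NG;SDS;SN;SNS;TKW
MQTL_4A_3	4A	wPt-3374	wmc0258	88.37	0.3	FWA;GL;GPC;GPL;HW;MDR;NG;SDS;TKW
MQTL_4A_4	4A	wmc776	wPt-9305	105.92	1.62	FWA;GCuC;GL;GPL;HW;LDMA;NG;SDS;SNS;TKW
MQTL_4A_5	4A	Xgwm832	Xmag3733	135.87	0.71	FWA;GCuC
MQTL_4B_1	4B	wPt-0037	wmc0047	9.07	4.66	DA;DPM;HW;MTI;PH;SD;SDS
MQTL_4B_2	4B	wPt-3608	wmc125	11.84	3.76	DA;DPM;HW;MTI;PH;SD;SDS
MQTL_4B_3	4B	gwm0149	Xcfd222	19.71	7.9	GN;GY;HW;KW;MTI;PH;SD;SDS;TKW
MQTL_4B_4	4B	wmc710	Xbarc1096	28.20	0.01	GN;HW;KW;MTI;PDMA;PH;SD;SDS;TKW
MQTL_4D_1	4D	Rht-D1	wmc285	17.98	1.87	GCuC;GFeC;GMnC;GY;SN;SNS
MQTL_4D_2	4D	wPt-732586	Xsrap11a	41.00	2.06	GFeC;GMnC;GZnC;SN
MQTL_4D_3	4D	cfd65	gwm609	100.02	5.4	GFeC;GMnC;GSeC;SD
MQTL_4D_4	4D	barc108	Xbarc1183	172.97	6.6	GFeC;GZnC
MQTL_5A_1	5A	wPt-6048	barc10	1.87	4.02	DA;DPM;PT
MQTL_5A_2	5A	Xcwem32.2	wmc59	46.08	5.03	DPM;LDMA
MQTL_5A_3	5A	Xbarc358.2	barc40	69.46	3.35	75%G;DA;DPM;GFD;MRS;PH;SHS;SW
MQTL_5A_4	5A	wPt-9834	gwm126	78.56	3.22	75%G;DA;DPM;GFeC;GWe;GY;LS;LY;MRS;SHS
MQTL_5A_5	5A	gwm595	Xbarc247	88.51	5.49	GFeC;GZnC
MQTL_5B_1	5B	cfd5	BE404594-175	0.00	1.65	DPM
MQTL_5B_2	5B	BE404594-175	wmc773	2.20	1.07	GY
MQTL_5B_3	5B	wPt-6135	gwm540	16.10	4.55	DH;GY;SL;TKW
MQTL_5B_4	5B	gdm116	gwm271	40.43	0.28	DH;GFD;GY;LDMA
MQTL_5D_1	5D	Xgdm99.2	Xbarc286	40.43	4.17	25%G;KL;PGMS;SNS
MQTL_5D_2	5D	cfa2104	ww152	47.41	0.34	25%G;DST;GPC;HW;GY;KH;KL;NG;PGMS;SN;WGC
MQTL_6A_1	6A	wPt-1381	wPt-0938	16.14	5.04	GWe;PH;TKW
MQTL_6A_2	6A	agg/cat-6	wPt-2636	26.8	2.68	NG;PDMA;SNS
MQTL_6A_3	6A	Xgwm82	wmc807	58.75	5.2	BM;NG;SNS
MQTL_6A_4	6A	Xgwm732	Xswes123.3	72.28	2.11	SNS
MQTL_6A_5	6A	wmc206	cwem49f	108.86	3.32	SNS;TKW
MQTL_6B_1	6B	gctg/ctt-1	agc/tgc-3	48.00	7	GY;MDR
MQTL_6B_2	6B	Dupw216	aca/ctga-7	77.00	5.1	DH
MQTL_6B_3	6B	act/gcg-11	agc/tgc-7	93.87	2.71	SHS;SW
MQTL_6B_4	6B	wPt-7662	gwm613	120.97	4.47	DA;PH
MQTL_6B_5	6B	wmc486	wmc487	130.30	5.1	PGMS;PH;TKW
MQTL_6B_6	6B	wPt-2786	barc0045	138.66	4.87	GY;PGMS;TKW
MQTL_6B_7	6B	cfa2110	agc/ctc-6	159.43	5.9	GY;PGMS;TKW;TMRS
MQTL_6B_8	6B	barc0247	wPt-1325	184.32	15.62	NG;PGMS
MQTL_6D_1	6D	cfd0049	Xswes123.6	8.23	19.83	PT;SN
MQTL_6D_2	6D	Xswes123.7	Xcft3103	43.93	15.84	GY;SN
MQTL_6D_3	6D	wmc749	barc175	65.91	6.6	GY;NG;SN
MQTL_6D_4	6D	Xcfa2114	gpw95010	85.38	21.45	GY;SN
MQTL_7A_1	7A	wmc497	wPt-6217	45.93	1.82	CID;DA;DGC;DPM;GFD;GFeC;GPC;GZnC;KH;NG;PH;PT;SDS;SL;SNS;TKW
MQTL_7A_2	7A	cfd13	gwm4	51.07	1.48	CID;DA;DGC;DPM;GFD;GFeC;GPC;GZnC;KH;LS;NG;PH;PT;SDS;SHS;SNS;TKW;TMRS
MQTL_7A_3	7A	Xwmc475.1	cfa2257	59.28	0.75	CID;DA;DGC;DPM;GFD;GFeC;GPC;GY;GZnC;KH;NG;PH;PT;SDS;SHS;SL;SNS;TKW
MQTL_7A_4	7A	wPt-1259	Xmag2931.3	74.58	3.1	DGC;GPC;KH;PH;SDS;TKW
MQTL_7B_1	7B	U260	gwm569	61.32	4.04	50%G;DH;DPM;GFeC;GL/GW;GPL;NG;SL
MQTL_7B_2	7B	wPt-4342	wPt-7813	72.66	0.89	50%G;DH;DPM;GFD;GFeC;GFR;GL/GW;GPL;GY;GZnC;KH;NG;PH;SD;SL;TKW;TMRS
MQTL_7B_3	7B	wPt-6372	barc176	83.18	2.37	50%G;DH;DPM;GCuC;GFeC;GFR;GL/GW;GPL;GY;KH;NG;PH;SL;TKW
MQTL_7B_4	7B	Xcau12.3	barc126	98.82	8.22	50%G;DPM;GFeC;GL/GW;GPL;GY;KH;PH;TKW
MQTL_7B_5	7B	Xbarc1073.2	wmc10	121.38	3.87	GFeC;GL/GW;GPL;KH;NG;SN;SNS;TKW
MQTL_7B_6	7B	Xgwm3036	gwm146	132.26	2.72	GFeC;GL/GW;GPL;NG;SNS;TKW
MQTL_7D_1	7D	wmc121	wmc489	89.41	4.94	50%G;SD;TMRS
MQTL_7D_2	7D	wmc473	wmc94	98.52	5.16	GY;SD
MQTL_7D_3	7D	gtg/cagt-4	wmc824	121.60	3.82	LY;PH
MQTL_7D_4	7D	barc53	cfd0083	149.45	35.94	SHS
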