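# SYNTHETIC stand-in ortholog pairs: the published syntenic table lists
# interval coordinates but not the supporting gene coordinates, so one
# ortholog pair per syntenic row is placed at the interval midpoints
# (gene length = 10% of interval width, capped at 2 kb).
gene_a	species_a	chr_a	start_a	end_a	gene_b	species_b	chr_b	start_b	end_b
TaSynOrtho01	wheat	7B	674.199585	674.199915	OsSynOrtho01	rice	6	3.10497	3.10543
TaSynOrtho02	wheat	3B	828.59165	828.59365	OsSynOrtho02	rice	1	25.047365	25.047735
TaSynOrtho03	wheat	4D	459.68623	459.68637	OsSynOrtho03	rice	3	14.681435	14.681665
TaSynOrtho04	wheat	5A	700.177965	700.178135	OsSynOrtho04	rice	11	10.47616	10.47644
TaSynOrtho05	wheat	1B	27.150045	27.150055	ZmSynOrtho05	maize	1	224.721645	224.721655
TaSynOrtho06	wheat	2A	82.18624	82.18656	ZmSynOrtho06	maize	5	19.22386	19.22414
TaSynOrtho07	wheat	4A	647.09019	647.09081	ZmSynOrtho07	maize	1	275.02416	275.02484
TaSynOrtho08	wheat	4B	649.47223	649.47277	ZmSynOrtho08	maize	8	47.14749	47.14831
TaSynOrtho09	wheat	4B	518.097315	518.097785	ZmSynOrtho09	maize	2	122.677165	122.677535
TaSynOrtho10	wheat	7B	576.0464	576.0484	OsSynOrtho10	rice	6	29.18395	29.18595
TaSynOrtho11	wheat	7B	575.6525	575.6545	ZmSynOrtho11	maize	5	57.01505	57.01705
TaSynOrtho12	wheat	7B	573.9657	573.9677	ZmSynOrtho12	maize	6	90.12105	90.12305
TaSynOrtho13	wheat	4B	627.72795	627.72995	OsSynOrtho13	rice	3	2.0428	2.0448
TaSynOrtho14	wheat	7B	741.57101	741.57119	OsSynOrtho14	rice	10	13.36122	13.36158
TaSynOrtho15	wheat	3D	33.295395	33.295505	ZmSynOrtho15	maize	10	69.484185	69.484315
TaSynOrtho16	wheat	2A	88.29607	88.29633	OsSynOrtho16	rice	7	7.395895	7.396205
TaSynOrtho17	wheat	4D	484.685855	484.686245	OsSynOrtho17	rice	6	21.398035	21.398265
TaSynOrtho18	wheat	4D	461.491295	461.491605	OsSynOrtho18	rice	7	20.0276	20.0296
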