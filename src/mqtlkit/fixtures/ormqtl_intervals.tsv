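# Syntenic interval table for orthologous-MQTL detection: each row pairs a
# wheat MQTL sub-interval (Mb) with the co-linear rice or maize MQTL interval.
or_id	trait	wheat_mqtl	wheat_chr	wheat_start_mb	wheat_end_mb	other_mqtl	other_species	other_chr	other_start_mb	other_end_mb
OrMQTL_1	GY	MQTL_7B_2	7B	674.1981	674.2014	MQTL6-2	rice	6	3.1029	3.1075
OrMQTL_2	GY	MQTL_3B_4	3B	828.4199	828.7654	MQTL-YLD3	rice	1	25.0457	25.0494
OrMQTL_3	GY	MQTL_4D_1	4D	459.6856	459.6870	MQTL-YLD9	rice	3	14.6804	14.6827
OrMQTL_4	GY	MQTL_5A_4	5A	700.1772	700.1789	MQTL-YLD19	rice	11	10.4749	10.4777
OrMQTL_5	GY	MQTL_1B_1	1B	27.1500	27.1501	MQTL7	maize	1	224.7216	224.7217
OrMQTL_6	GY	MQTL_2A_1	2A	82.1848	82.1880	MQTL29	maize	5	19.2226	19.2254
OrMQTL_7	GY	MQTL_4A_3	4A	647.0874	647.0936	MQTL10	maize	1	275.0211	275.0279
OrMQTL_8	GY	MQTL_4B_2	4B	649.4698	649.4752	MQTL44	maize	8	47.1438	47.1520
OrMQTL_9	GY	MQTL_4B_3	4B	518.0952	518.0999	MQTL23	maize	2	122.6755	122.6792
OrMQTL_10	GY	MQTL_7B_3	7B	569.4388	582.6560	MQTL-YLD14	rice	6	28.8459	29.5240
OrMQTL_10	GY	MQTL_7B_3	7B	568.6510	582.6560	MQTL5.5	maize	5	55.3131	58.7190
OrMQTL_10	GY	MQTL_7B_3	7B	568.1069	579.8265	MQTL66	maize	6	89.3129	90.9312
OrMQTL_11	PH	MQTL_4B_1	4B	619.5886	635.8693	MQTL-PH11	rice	3	1.8624	2.2252
OrMQTL_12	PH	MQTL_7B_5	7B	741.5702	741.5720	MQTL-PH26	rice	10	13.3596	13.3632
OrMQTL_13	PH	MQTL_3D_3	3D	33.2949	33.2960	MQTL107	maize	10	69.4836	69.4849
OrMQTL_14	GFeC,GZnC	MQTL_2A_1	2A	88.2949	88.2975	rMQTL7.1	rice	7	7.3945	7.3976
OrMQTL_15	GFeC,GZnC	MQTL_4D_1	4D	484.6841	484.6880	rMQTL6.3	rice	6	21.3970	21.3993
OrMQTL_15	GFeC,GZnC	MQTL_4D_1	4D	461.4899	461.4930	rMQTL7.2	rice	7	19.9760	20.0812
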