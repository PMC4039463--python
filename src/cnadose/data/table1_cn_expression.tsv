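# per-tumor copy-number burden and expression-status counts (31 tumors;
# 4 tumors lack expression data and have empty count columns)
tumor	pct_genome	genes_cn_altered	cn1_n	cn1_ex	cn3_n	cn3_ex	cn13_n	cn13_ex	cn2_n	cn2_ex	all_ex
R035	7.7	3640	301	70	1799	423	2100	493	18936	2178	2671
R062	8.3	2737
R072	5.3	1672	540	44	467	75	1007	119	20027	2284	2403
R075	1.2	368	0	0	225	25	225	25	20809	2183	2208
R111	7.7	2976
R116	3	1033
R154	7	2554	779	48	783	113	1562	161	19475	1924	2085
R183	6.5	2336	897	81	522	137	1419	218	19615	2577	2795
R189	18.6	5778	1558	163	1646	219	3204	382	17833	1875	2257
R194	0	0	0	0	0	0	0	0	21034	2681	2681
R198	24.8	8826	2044	163	3078	614	5122	777	15915	1618	2395
R208	0.2	125	0	0	63	9	63	9	20971	1771	1780
R221	0.7	183	62	4	43	4	105	8	20929	1460	1468
R240	1.5	631	253	13	127	9	380	22	20655	1276	1298
R244	0	0	0	0	0	0	0	0	21034	908	908
R248	0	0
R260	3.5	1295	208	14	560	75	768	89	20270	1615	1704
R282	11	4337	1438	144	1116	194	2554	338	18484	1931	2269
R298	19.6	6762	1235	112	2675	459	3910	571	17125	1483	2054
R322	9.4	2559	264	20	1065	91	1329	111	19708	1441	1552
R365	32.2	10666	3618	551	2471	381	6089	932	14950	1597	2529
R369	0.9	96	0	0	52	9	52	9	20983	1666	1675
R380	2.7	862	29	1	437	63	466	64	20568	2062	2126
R386	16.2	5349	723	56	2248	225	2971	281	18066	1040	1321
R392	2	465	51	6	182	23	233	29	20802	1310	1339
R444	0	0	0	0	0	0	0	0	21034	1646	1646
R476	0.2	197	145	7	0	0	145	7	20889	1854	1861
R478	1.2	1205	900	27	6	1	906	28	20129	1041	1069
R483	17.1	6030	2407	265	1137	138	3544	403	17495	1555	1958
R494	22.1	6846	2456	521	1371	199	3827	720	17209	2146	2866
R496	20.9	5856	1569	445	1626	264	3195	709	17841	2648	3357
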