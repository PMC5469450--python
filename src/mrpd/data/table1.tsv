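variant_id	chromosome	position	effect_allele	other_allele	eaf	beta_bmi	se_bmi	p_bmi	beta_pd	se_pd	p_pd
rs17001654	4	77348592	G	C	0.154	0.030	0.005	7.76e-09	-0.077	0.024	0.0014
rs13107325	4	103407732	T	C	0.072	0.047	0.007	1.83e-12	-0.109	0.032	0.0007
rs4787491	16	29922838	G	A	0.509	0.015	0.003	2.7e-08	-0.031	0.016	0.0508
rs4740619	9	15624326	T	C	0.540	0.017	0.003	4.56e-09	-0.029	0.017	0.0777
rs2820292	1	200050910	C	A	0.547	0.018	0.003	1.83e-10	-0.031	0.016	0.0587
rs1808579	18	19358886	C	T	0.534	0.016	0.003	4.17e-08	-0.027	0.016	0.0913
rs3888190	16	28796987	A	C	0.397	0.031	0.003	3.14e-23	-0.045	0.017	0.0076
rs2033732	8	85242264	C	T	0.749	0.018	0.003	4.89e-08	-0.023	0.019	0.2352
rs6465468	7	95007450	T	G	0.300	0.016	0.003	4.98e-08	-0.020	0.019	0.2844
rs12401738	1	78219349	A	G	0.347	0.020	0.003	1.15e-10	-0.023	0.017	0.1812
rs1000940	17	5223976	G	A	0.320	0.018	0.003	1.28e-08	-0.020	0.017	0.2477
rs6091540	20	50521269	C	T	0.725	0.019	0.003	2.15e-11	-0.020	0.018	0.2659
rs11727676	4	145878514	T	C	0.911	0.037	0.006	2.55e-08	-0.037	0.042	0.3745
rs16851483	3	142758126	T	G	0.066	0.048	0.008	3.55e-10	-0.046	0.033	0.1647
rs10968576	9	28404339	G	A	0.315	0.025	0.003	6.61e-14	-0.024	0.017	0.1669
rs10132280	14	24998019	C	A	0.674	0.022	0.003	1.14e-11	-0.021	0.018	0.2513
rs492400	2	219057996	C	T	0.426	0.015	0.003	6.78e-09	-0.014	0.017	0.4062
rs7899106	10	87400884	G	A	0.057	0.038	0.007	2.96e-08	-0.034	0.039	0.3811
rs1441264	13	78478920	A	G	0.613	0.017	0.003	2.96e-08	-0.015	0.016	0.3631
rs3101336	1	72523773	C	T	0.611	0.032	0.003	2.66e-26	-0.026	0.016	0.1203
rs13078960	3	85890280	G	T	0.193	0.029	0.004	1.74e-14	-0.022	0.020	0.2624
rs17094222	10	102385430	C	T	0.209	0.025	0.004	5.94e-11	-0.019	0.020	0.3432
rs11165643	1	96696685	T	C	0.574	0.022	0.003	2.07e-12	-0.016	0.016	0.3277
rs12940622	17	76230166	G	A	0.572	0.018	0.003	2.49e-09	-0.012	0.016	0.4607
rs11030104	11	27641093	A	G	0.791	0.042	0.004	5.56e-28	-0.027	0.020	0.178
rs7599312	2	213121476	G	A	0.721	0.021	0.003	1.17e-10	-0.013	0.018	0.4813
rs6567160	18	55980115	C	T	0.236	0.056	0.004	3.93e-53	-0.030	0.019	0.1144
rs2176040	2	226801046	A	G	0.362	0.015	0.003	9.99e-09	-0.008	0.017	0.6443
rs1516725	3	187306698	C	T	0.869	0.045	0.004	1.89e-22	-0.022	0.024	0.348
rs17724992	19	18315825	A	G	0.743	0.020	0.003	3.42e-08	-0.009	0.018	0.6166
rs7715256	5	153518086	G	T	0.422	0.017	0.003	8.85e-09	-0.008	0.016	0.6363
rs12429545	13	53000207	A	G	0.135	0.032	0.004	1.09e-12	-0.011	0.024	0.644
rs1558902	16	52361075	A	T	0.409	0.081	0.003	7.51e-153	-0.022	0.017	0.1859
rs17203016	2	207963763	G	A	0.195	0.021	0.004	3.41e-08	-0.006	0.021	0.7884
rs657452	1	49362434	A	G	0.397	0.023	0.003	5.48e-13	-0.006	0.017	0.7212
rs1460676	2	164275935	C	T	0.179	0.021	0.004	4.98e-08	-0.005	0.022	0.8204
rs6804842	3	25081441	G	A	0.569	0.018	0.003	2.48e-09	-0.004	0.016	0.7945
rs4256980	11	8630515	G	C	0.638	0.021	0.003	2.9e-11	-0.005	0.017	0.7876
rs1528435	15	65864222	T	C	0.631	0.018	0.003	1.2e-08	-0.004	0.017	0.8292
rs16951275	2	181259207	T	C	0.771	0.030	0.004	1.91e-17	-0.006	0.019	0.7585
rs10182181	2	25003800	G	A	0.468	0.031	0.003	8.78e-24	-0.006	0.016	0.7275
rs17024393	1	109956211	C	T	0.043	0.061	0.008	7.03e-14	-0.010	0.049	0.8327
rs3817334	11	47607569	T	C	0.401	0.026	0.003	5.15e-17	-0.004	0.016	0.8003
rs1928295	9	119418304	T	C	0.550	0.018	0.003	7.91e-10	-0.003	0.016	0.8747
rs2112347	5	75050998	T	G	0.621	0.025	0.003	6.19e-17	-0.003	0.022	0.9055
rs2365389	3	61211502	C	T	0.572	0.020	0.003	1.63e-10	-0.001	0.017	0.9654
rs758747	16	3567359	T	C	0.280	0.023	0.004	7.47e-10	0.000	0.018	0.9996
rs13201877	6	137717234	G	A	0.140	0.024	0.004	4.29e-08	0.003	0.026	0.9138
rs7138803	12	48533735	A	G	0.379	0.032	0.003	8.15e-24	0.005	0.017	0.7605
rs2287019	19	50894012	C	T	0.806	0.035	0.004	4.59e-18	0.007	0.020	0.7198
rs2207139	6	50953449	G	A	0.176	0.045	0.004	4.13e-29	0.011	0.021	0.6064
rs17405819	8	76969139	T	C	0.702	0.022	0.003	2.07e-11	0.006	0.017	0.7158
rs10938397	4	44877284	G	A	0.428	0.040	0.003	3.21e-38	0.014	0.016	0.4092
rs29941	14	78969207	G	A	0.670	0.018	0.003	2.41e-08	0.006	0.017	0.7122
rs7141420	19	39001372	T	C	0.529	0.023	0.003	1.23e-14	0.008	0.017	0.6259
rs2033529	6	40456631	G	A	0.289	0.018	0.003	1.39e-08	0.006	0.018	0.7176
rs6477694	9	110972163	C	T	0.371	0.017	0.003	2.67e-08	0.006	0.017	0.7016
rs13021737	2	622348	G	A	0.830	0.060	0.004	1.11e-50	0.023	0.021	0.2741
rs1167827	7	75001105	G	A	0.557	0.020	0.003	6.33e-10	0.009	0.016	0.6014
rs7903146	10	114748339	C	T	0.713	0.024	0.003	1.11e-11	0.011	0.018	0.531
rs543874	1	176156103	G	A	0.195	0.050	0.004	2.62e-35	0.025	0.020	0.2265
rs205262	6	34671142	G	A	0.285	0.021	0.003	1.75e-10	0.011	0.018	0.5442
rs11057405	12	121347850	G	A	0.902	0.030	0.005	2.02e-08	0.018	0.030	0.5438
rs7239883	18	38401669	G	A	0.394	0.015	0.003	1.51e-08	0.010	0.016	0.5618
rs2836754	21	39213610	C	T	0.599	0.017	0.003	1.61e-08	0.011	0.017	0.5139
rs12286929	11	114527614	G	A	0.523	0.021	0.003	1.31e-12	0.014	0.016	0.3858
rs2176598	11	43820854	T	C	0.256	0.019	0.003	2.97e-08	0.013	0.018	0.4701
rs3736485	15	49535902	A	G	0.461	0.016	0.003	7.41e-09	0.013	0.016	0.435
rs10733682	9	128500735	A	G	0.475	0.019	0.003	1.83e-08	0.017	0.016	0.2755
rs13191362	6	162953340	A	G	0.880	0.029	0.005	7.34e-09	0.035	0.025	0.1626
rs9374842	6	120227364	T	C	0.748	0.020	0.003	2.67e-08	0.026	0.019	0.1726
rs887912	2	59075742	T	C	0.317	0.023	0.003	2.75e-11	0.031	0.018	0.0738
rs9540493	13	65103705	A	G	0.464	0.018	0.003	4.97e-08	0.025	0.017	0.1389
rs977747	1	47457264	C	G	0.403	0.017	0.003	2.18e-08	0.024	0.016	0.1368
rs2121279	2	142759755	T	C	0.150	0.024	0.004	2.31e-08	0.037	0.024	0.1217
rs9400239	6	109084356	C	T	0.673	0.017	0.003	1.61e-08	0.028	0.018	0.118
rs3849570	3	81874802	A	C	0.362	0.018	0.003	2.6e-08	0.030	0.017	0.0815
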