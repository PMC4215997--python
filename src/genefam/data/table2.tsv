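gene_a	gene_b	mode	fragment_class	ka	ks	ratio	date_mya
Gmcupin5.1	Gmcupin8.1	Fragment	Large	0.0370	0.1177	0.3144	9.65
Gmcupin9.1	Gmcupin15.1	Fragment	Large	0.0328	0.1441	0.2276	11.81
Gmcupin3.1	Gmcupin19.13	Fragment	Large	0.0576	0.1479	0.3895	12.12
Gmcupin10.5	Gmcupin20.1	Fragment	Small	0.0181	0.1073	0.1687	8.80
Gmcupin1.1	Gmcupin2.2	Fragment	Large	0.0161	0.1972	0.0816	16.16
Gmcupin10.1	Gmcupin13.3	Fragment	Large	0.0457	0.1493	0.3061	12.24
Gmcupin13.1	Gmcupin17.1	Fragment	Small	0.1186	0.1838	0.6453	15.07
Gmcupin7.1	Gmcupin16.1	Fragment	Large	0.0173	0.1582	0.1094	12.97
Gmcupin16.2	Gmcupin7.4	Fragment	Large	0.0404	0.1916	0.2109	15.70
Gmcupin4.1	Gmcupin6.1	Fragment	Large	0.1079	0.2469	0.4370	20.24
Gmcupin8.2	Gmcupin15.4	Fragment	Small	0.0290	0.0965	0.3005	7.91
Gmcupin10.7	Gmcupin20.3	Fragment	Large	0.0270	0.1925	0.1403	15.78
Gmcupin10.6	Gmcupin20.4	Fragment	Large	0.0330	0.1511	0.2184	12.39
Gmcupin16.8	Gmcupin19.12	Fragment	Small	0.2215	0.3497	0.6334	28.66
Gmcupin19.13	Gmcupin3.1	Fragment	Large	0.0576	0.1479	0.3895	12.12
Gmcupin13.4	Gmcupin15.1	Fragment	Large	0.0658	0.1742	0.3777	14.28
Gmcupin19.15	Gmcupin3.2	Fragment	Large	0.0239	0.1799	0.1329	14.75
Gmcupin10.3	Gmcupin10.4	Tandem Repeat	n/a	0.0351	0.0909	0.3861	7.45
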