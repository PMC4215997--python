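gene_id	locus	transcript	chromosome	start_raw	end_raw	aa_length	n_exons
Gmcupin01.1	Glyma01g04450	Glyma01g04450.1	Gm01	3990477	3991986	220	1
Gmcupin02.1	Glyma02g01085	Glyma02g01085.1	Gm02	816290	817482	147	2
Gmcupin02.2	Glyma02g03100	Glyma02g03100.1	Gm02	2414696	2415880	220	1
Gmcupin02.3	Glyma02g05010	Glyma02g05010.1	Gm02	4077995	4078612	205	1
Gmcupin03.1	Glyma03g32030	Glyma03g32030.1	Gm03	39840052	39842763	495	4
Gmcupin03.2	Glyma03g38630	Glyma03g38630.1	Gm03	44934345	44933730	218	2
Gmcupin04.1	Glyma04g39040	Glyma04g39040.2	Gm04	45306333	45307231	199	3
Gmcupin05.1	Glyma05g25620	Glyma05g25620.1	Gm05	31685194	31686123	215	2
Gmcupin06.1	Glyma06g15930	Glyma06g15930.1	Gm06	12516557	12517688	228	1
Gmcupin07.1	Glyma07g04310	Glyma07g04310.1	Gm07	3163391	3164534	209	1
Gmcupin07.2	Glyma07g04320	Glyma07g04320.1	Gm07	3167203	3168078	208	1
Gmcupin07.3	Glyma07g04330	Glyma07g04330.1	Gm07	3173276	3174394	208	1
Gmcupin07.4	Glyma07g04340	Glyma07g04340.1	Gm07	3179749	3180833	225	1
Gmcupin07.5	Glyma07g04400	Glyma07g04400.1	Gm07	3202414	3203532	208	1
Gmcupin08.1	Glyma08g08600	Glyma08g08600.1	Gm08	6134739	6134464	215	2
Gmcupin08.2	Glyma08g24320	Glyma08g24320.1	Gm08	18508831	18509842	211	1
Gmcupin09.1	Glyma09g03010	Glyma09g03010.1	Gm09	2110529	2109847	217	2
Gmcupin09.2	Glyma09g08030	Glyma09g08030.1	Gm09	7066672	7066667	135	1
Gmcupin10.1	Glyma10g08360	Glyma10g08360.1	Gm10	7201264	7200871	226	2
Gmcupin10.2	Glyma10g11935	Glyma10g11935.1	Gm10	12509357	12509734	125	1
Gmcupin10.3	Glyma10g28010	Glyma10g28010.1	Gm10	36807794	36807686	221	2
Gmcupin10.4	Glyma10g28020	Glyma10g28020.1	Gm10	36812065	36811696	220	2
Gmcupin10.5	Glyma10g28190	Glyma10g28190.1	Gm10	36981942	36980791	223	2
Gmcupin10.6	Glyma10g31200	Glyma10g31200.2	Gm10	39762112	39761524	198	3
Gmcupin10.7	Glyma10g31210	Glyma10g31210.1	Gm10	39768393	39768098	232	2
Gmcupin10.8	Glyma10g42611	Glyma10g42611.1	Gm10	49519941	49520574	177	3
Gmcupin12.1	Glyma12g09630	Glyma12g09630.2	Gm12	7391558	7392181	207	1
Gmcupin12.2	Glyma12g09640	Glyma12g09640.2	Gm12	7398088	7398957	212	2
Gmcupin12.3	Glyma12g09760	Glyma12g09760.2	Gm12	7531728	7532351	207	1
Gmcupin12.4	Glyma12g31110	Glyma12g31110.1	Gm12	34711894	34712517	207	1
Gmcupin13.1	Glyma13g16960	Glyma13g16960.2	Gm13	20815056	20816399	199	2
Gmcupin13.2	Glyma13g18450	Glyma13g18450.2	Gm13	22109247	22113254	226	4
Gmcupin13.3	Glyma13g22050	Glyma13g22050.1	Gm13	25624544	25624397	239	2
Gmcupin13.4	Glyma13g40360	Glyma13g40360.1	Gm13	40856942	40859117	483	5
Gmcupin15.1	Glyma15g05040	Glyma15g05040.2	Gm15	3611464	3613757	351	7
Gmcupin15.2	Glyma15g13960	Glyma15g13960.1	Gm15	10534152	10533514	215	2
Gmcupin15.3	Glyma15g19510	Glyma15g19510.1	Gm15	16833879	16835243	213	1
Gmcupin15.4	Glyma15g35130	Glyma15g35130.1	Gm15	39672342	39673419	231	1
Gmcupin16.1	Glyma16g00980	Glyma16g00980.1	Gm16	652712	653968	209	1
Gmcupin16.2	Glyma16g00990	Glyma16g00990.1	Gm16	656546	657171	181	2
Gmcupin16.3	Glyma16g01000	Glyma16g01000.1	Gm16	660570	661190	206	1
Gmcupin16.4	Glyma16g06500	Glyma16g06500.1	Gm16	5853241	5853122	221	2
Gmcupin16.5	Glyma16g06520	Glyma16g06520.1	Gm16	5858235	5858104	221	2
Gmcupin16.6	Glyma16g06530	Glyma16g06530.1	Gm16	5860996	5862104	220	2
Gmcupin16.7	Glyma16g06630	Glyma16g06630.1	Gm16	5947078	5946961	221	2
Gmcupin16.8	Glyma16g06640	Glyma16g06640.1	Gm16	5951136	5952363	215	2
Gmcupin16.9	Glyma16g07550	Glyma16g07550.1	Gm16	6838751	6839383	210	1
Gmcupin16.10	Glyma16g07560	Glyma16g07560.2	Gm16	6844140	6843743	188	1
Gmcupin16.11	Glyma16g07580	Glyma16g07580.1	Gm16	6860067	6860840	214	1
Gmcupin17.1	Glyma17g05760	Glyma17g05760.1	Gm17	4052453	4053577	208	1
Gmcupin19.1	Glyma19g09370	Glyma19g09370.2	Gm19	11189789	11189486	181	3
Gmcupin19.2	Glyma19g09810	Glyma19g09810.1	Gm19	11530120	11531183	221	2
Gmcupin19.3	Glyma19g09830	Glyma19g09830.1	Gm19	11554699	11555709	221	2
Gmcupin19.4	Glyma19g09840	Glyma19g09840.1	Gm19	11601504	11602281	221	2
Gmcupin19.5	Glyma19g09860	Glyma19g09860.1	Gm19	11630024	11631147	221	2
Gmcupin19.6	Glyma19g09990	Glyma19g09990.1	Gm19	11922733	11922620	221	2
Gmcupin19.7	Glyma19g24840	Glyma19g24840.1	Gm19	30509520	30510472	212	2
Gmcupin19.8	Glyma19g24850	Glyma19g24850.1	Gm19	30514099	30513955	221	2
Gmcupin19.9	Glyma19g24870	Glyma19g24870.2	Gm19	30532519	30533617	221	2
Gmcupin19.10	Glyma19g24900	Glyma19g24900.1	Gm19	30559228	30560036	221	2
Gmcupin19.11	Glyma19g24910	Glyma19g24910.1	Gm19	30576453	30577383	219	2
Gmcupin19.12	Glyma19g27580	Glyma19g27580.1	Gm19	34882234	34884637	212	2
Gmcupin19.13	Glyma19g34780	Glyma19g34780.1	Gm19	42366324	42369290	481	4
Gmcupin19.14	Glyma19g41070	Glyma19g41070.2	Gm19	47390045	47391131	184	3
Gmcupin19.15	Glyma19g41220	Glyma19g41220.1	Gm19	47524955	47524382	219	2
Gmcupin20.1	Glyma20g22180	Glyma20g22180.1	Gm20	32106832	32105935	224	2
Gmcupin20.2	Glyma20g25430	Glyma20g25430.1	Gm20	35111115	35111738	207	1
Gmcupin20.3	Glyma20g36300	Glyma20g36300.1	Gm20	44453211	44454264	232	2
Gmcupin20.4	Glyma20g36320	Glyma20g36320.1	Gm20	44458621	44459718	222	2
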