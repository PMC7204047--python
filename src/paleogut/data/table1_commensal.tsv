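phylum	genus	elpc	brs1_sc1	brs2	brs3	brs4	brs5_sc2	total	brs_im_total	mean_read_length_bp	p_brs1	p_brs2	p_brs3	p_brs4	p_brs5
Euryarchaeota	Methanobrevibacter	19	7	1952	1109	29147	69	32303	32208	70.60	NA	0.193028900	0.073998830	0.002632932	0.567650800
Actinobacteria	Cellulomonas	0	65	3445	1626	54666	143	59945	59737	66.60	0.921500700	0.002823314	0.153993200	0.006118848	0.509736300
Actinobacteria	Slackia	0	5	89	29	1343	8	1474	1461	61.80	0.007399490	0.935197800	0.311623400	0.508960500	NA
Bacteroidetes	Alistipes	2	4	139	46	1069	15	1275	1254	65.40	0.675706100	0.420822200	0.053055550	0.031112450	0.606658100
Bacteroidetes	Bacteroides	5	114	28316	10115	115446	162	154158	153877	72.20	0.721165000	0.001696204	0.000000390	0.000622655	0.142918300
Bacteroidetes	Flavobacterium	32	58	6986	3125	33452	72	43725	43563	64.40	0.216522900	0.000235190	0.000039500	0.022810540	0.921151200
Bacteroidetes	Pedobacter	1	23	1656	715	9663	19	12077	12034	62.80	0.500000000	0.001704170	0.075530930	0.062391830	0.161709000
Bacteroidetes	Prevotella	17	48	418	184	3712	43	4422	4314	61.00	0.099233850	0.305674400	0.081571890	0.016625350	0.631959800
Firmicutes	Blautia	15	72	276	124	3640	111	4238	4040	68.20	0.608740100	0.084446270	0.428864300	0.045772080	0.245663300
Firmicutes	Butyrivibrio	0	8	325	127	3082	6	3548	3534	58.20	0.395839900	0.037614750	0.109365700	0.273060200	0.580047400
Firmicutes	Clostridium	4	148	2671	1304	29948	135	34210	33923	65.80	0.074740200	0.296300200	0.190844300	0.015163840	0.360285900
Firmicutes	Enterococcus	1	156	553	298	7427	20	8455	8278	74.60	0.003765520	0.333696100	0.022915900	0.274913800	NA
Firmicutes	Eubacterium	0	40	697	296	9029	51	10113	10022	65.80	0.106194500	0.004360991	0.056443760	0.024325710	0.246347100
Firmicutes	Lactobacillus	0	143	0	259	6728	14	7144	6987	69.00	0.157217100	NA	0.011884140	0.903384000	NA
Firmicutes	Lactococcus	12	118	595	361	6219	14	7319	7175	69.60	0.463765800	0.006836895	0.033206520	0.000000013	NA
Firmicutes	Mogibacterium	0	7	176	76	2116	5	2380	2368	68.60	0.499997800	0.228221200	0.019403830	0.008329356	0.188080100
Firmicutes	Oribacterium	1	12	170	72	2018	2	2275	2260	64.60	0.167621400	0.050161290	0.349725600	0.000162173	NA
Firmicutes	Oscillibacter	0	7	165	91	1787	12	2062	2043	63.00	0.120518600	0.009668940	0.349725600	0.095004240	0.072742730
Firmicutes	Ruminococcus	18	42	1119	464	9229	100	10972	10812	67.40	0.271433200	0.048583730	0.738132500	0.001960024	0.300862800
Firmicutes	Sarcina	0	3	508	202	327	2	1042	1037	67.00	NA	0.413740500	0.018963150	0.025439260	NA
Proteobacteria	Enterobacter	0	145	41220	14798	181051	205	237419	237069	71.80	0.004146302	0.000377506	0.000009640	0.001112472	0.132896300
Proteobacteria	Klebsiella	14	21	3485	1217	15633	72	20442	20335	70.00	0.529037900	0.001153996	0.001264576	0.000436448	0.921151200
Proteobacteria	Sphingobium	0	36	1023	458	8330	84	9931	9811	65.80	0.126796900	0.132801100	0.045433740	0.000753091	0.602973600
Proteobacteria	Variovorax	0	112	2099	878	16970	315	20374	19947	69.60	0.259295700	0.005879342	0.057844450	0.020613870	0.171048100
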