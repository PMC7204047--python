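phylum	genus	clinical_manifestations	elpc	brs1_sc1	brs2	brs3	brs4	brs5_sc2	total	mean_read_length_bp	p_brs1	p_brs2	p_brs3	p_brs4	p_brs5
Actinobacteria	Mycobacterium	Tuberculosis, leprosy, atypical infections	701	397	4535	1853	59096	487	67069	67.20	0.0707802	0.0017862	0.0037356	0.0100530	0.2953064
Bacteroidetes	Weeksella	Pneumonia, sepsis, peritonitis, urinary tract infections	1	0	461	175	2552	0	3189	45.40	NA	0.0069370	0.0484237	0.1960360	NA
Firmicutes	Listeria	Listeriosis (convulsions, septicaemia and meningitis)	0	92	453	233	5989	5	6772	72.80	0.0000005	0.3494000	0.0975000	0.8800000	NA
Proteobacteria	Aeromonas	Gastroenteritis and wound infections	0	13	129	289	2033	29	2493	67.20	0.2264910	0.0206110	0.4139431	0.0060921	0.4998525
Proteobacteria	Achromobacter	Skin, soft tissue and respiratory infections	21	150	36089	12869	160087	311	209527	72.40	0.0011408	0.0017379	0.0000094	0.0015504	0.1190260
Proteobacteria	Bordetella	Pertussis (whooping cough, respiratory infection)	18	123	2027	683	16466	196	19513	69.60	0.0204611	0.1325985	0.0082522	0.0077918	0.2557714
Proteobacteria	Burkholderia	Pulmonary infections (pneumonia, melioidosis)	12	48	869	287	6965	156	8337	62.00	0.2711432	0.0462580	0.2140947	0.3505477	0.1594083
Proteobacteria	Comamonas	Acute appendicitis, urinary tract infection	8	79	3656	1467	40820	987	47017	73.40	0.6379285	0.0059303	0.0225115	0.0322217	0.6381353
Proteobacteria	Delftia	Endocarditis, skin an ocular infections	226	594	921	348	10552	692	13333	74.80	0.2733595	0.0035008	0.5813131	0.0712462	0.0567663
Proteobacteria	Lysobacter	Opportunistic pathogen, various symptoms	5	37	9616	3170	45813	95	58736	66.20	0.2478419	0.0013587	0.0003318	0.0064930	0.8210803
Proteobacteria	Shigella	Shigellosis (dysentery, seizures, mucosal ulceration)	2	253	35046	12402	137623	762	186088	76.80	0.5381291	0.0002471	0.0000002	0.0002182	0.2954809
Proteobacteria	Vibrio	Cholera (gastroenteritis, diarrhoea, septicaemia)	0	7	419	147	2333	21	2927	62.80	NA	0.4420414	0.1131828	0.0005438	NA
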