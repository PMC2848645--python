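section	rs_id	substitution	ref_if_different	gene	isoform	position_label	ahp	homozygote	count	disease	flags
beta_sheet	61745307	I88M	-	MYH13	super-fast	near b1	-	-	-	0	-
beta_sheet	442275	E89Q	-	MYH6	alpha-cardiac	near b1	0.5	N	525	0	-
beta_sheet	61739660	H98Q	-	MYH1	2x	near b1	-	-	-	0	-
beta_sheet	2754166	D108E	E108	MYH7	beta-cardiac	near b1	0	N	525	0	-
beta_sheet	7737765	H170Y	R170	MYO10	myosin X	b4	-	-	-	0	-
beta_sheet	61745058	D171E	E171	MYH7B	beta-cardiac	b4	-	-	-	0	-
beta_sheet	61745059	N172D	-	MYH7B	beta-cardiac	b4	-	-	-	0	-
beta_sheet	45516091	R240W	-	MYH7	beta-cardiac	SW1	0	Y	0	0	zero_count
beta_sheet	28934610	R246H	-	MYO7A	myosin VIIA	SW1	-	-	-	0	-
beta_sheet	3218713	R252Q	-	MYH7	beta-cardiac	b6	0	Y	525	1	-
beta_sheet	55645295	I253V	-	MYH14	iso1/iso2	b6	-	-	-	0	-
beta_sheet	28936390	E257V	T257	MYO6	myosin VI	b6	-	-	-	0	-
beta_sheet	34416201	T258K	-	MYH13	super-fast	b6/b7	2.5	N	39	0	-
beta_sheet	4299484	R445Q	-	MYH15	unknown	near b7	18.0	?	1178	0	-
beta_sheet	61731179	N447K	-	MYH6	alpha-cardiac	near b7	-	-	-	0	-
beta_sheet	61745057	L463P	-	MYH7B	beta-cardiac	b5	-	-	-	0	-
beta_sheet	4981473	E469Q	-	MYH7	beta-cardiac	SW2	0	N	525	0	-
beta_sheet	28932773	R675Q	-	MYH8	perinatal	b3	-	-	-	1	-
beta_sheet	11539755	E681K	-	MYOIE	myosin 1e	near b3	-	-	-	0	-
switch2_helix	61734198	Q478H	-	MYH11	sm1A/sm2B	SW2 hx	-	-	-	0	-
switch2_helix	1064307	Y483H	F483	MYO9B	myosin IXB	SW2 hx	-	-	-	0	-
switch2_helix	28934903	N485I	-	MYO7A	myosin VIIA	SW2 hx	-	-	-	0	-
switch2_helix	61745301	H494D	-	MYH13	super-fast	SW2 hx	-	-	-	0	-
switch2_helix	9868484	H495Y	-	MYH15	unknown	SW2 hx	38.3	Y	1121	0	-
switch2_helix	1052031	F497L	-	MYO7A	myosin VIIA	SW2 hx	-	-	-	0	-
switch2_helix	3218715	E502K	-	MYH7	beta-cardiac	SW2 hx	0	Y	525	1	-
switch2_helix	3729813	K505N	-	MYH7	beta-cardiac	SW2 hx	0	N	525	0	-
hinge_converter_lever	73974725	M688V	-	MYH1	2x	SH2/SH1 hn	-	-	-	0	-
hinge_converter_lever	34515627	V694E	L694	MYO7A	myosin VIIA	SH2/SH1 hn	-	-	-	0	-
hinge_converter_lever	41298143	R695H	H695	MYO7A	myosin VIIA	SH2/SH1 hn	-	-	-	0	-
hinge_converter_lever	2190729	G701R	-	MYH13	super-fast	swivel	2.8	Y	384	0	-
hinge_converter_lever	28940307	R707S	-	MYH14	iso1/iso2	SH2/SH1 hn	-	-	-	0	-
hinge_converter_lever	3181426	R710S	-	MYH7	beta-cardiac	SH2/SH1 hn	-	-	-	0	-
hinge_converter_lever	35641839	V720I	-	MYO7A	myosin VIIA	Converter	-	-	-	1	-
hinge_converter_lever	1136661	Y723C	K723	MYO10	myosin X	Converter	-	-	-	1	-
hinge_converter_lever	3746442	P735S	-	MYH7B	beta-cardiac	Converter	-	Y	525	1	homozygous_all
hinge_converter_lever	26740	R743Q	K743	MYO10	myosin X	Converter	13.5	?	1122	0	-
hinge_converter_lever	11847151	L785M	-	MYH6	alpha-cardiac	Lever-Arm	0	N	525	0	-
hinge_converter_lever	36090425	D787N	Q787	MYO7A	myosin VIIA	Lever-Arm	-	-	-	0	-
hinge_converter_lever	3218716	A801T	-	MYH7	beta-cardiac	LA & ELC IQ	0	Y	690	1	-
sh3	17092199	P31T	-	MYH7B	beta-cardiac	SH3	-	?	1013	0	discordant
sh3	28711516	G57R	-	MYH6	alpha-cardiac	SH3	-	Y	-	0	-
sh3	17707947	V60I	-	MYO10	myosin X	SH3	12.9	?	1092	0	-
sh3	41309316	K68N	A68	MYH7B	beta-cardiac	SH3	-	-	-	0	-
actin_binding	45629132	R370H	K370	MYO7A	myosin VIIA	C-loop	-	-	-	0	-
actin_binding	35222064	Q371P	-	MYH13	super-fast	C-loop	2.5	N	39	0	-
actin_binding	2515926	P378Q	-	MYH6	alpha-cardiac	C-loop	-	-	-	0	-
actin_binding	3218714	R406W	-	MYH7	beta-cardiac	Myopathy	0	Y	525	1	-
actin_binding	45522831	R408C	K408	MYH7B	beta-cardiac	Myopathy	-	-	-	0	-
actin_binding	35349985	F534L	-	MYH4	2b	actin bind	2.8	N	39	0	-
actin_binding	59922029	R570K	K570	MYO10	myosin X	Loop 3	-	-	-	0	-
actin_binding	61735348	V572A/D	A572	MYH3	embryonic	Loop 3	-	-	-	0	-
actin_binding	28565077	A621V	-	MYH15	unknown	near Loop 2	-	-	-	0	-
actin_binding	61745053	T631N	E631	MYH7B	beta-cardiac	Loop 2	-	-	-	0	-
actin_binding	34693726	A637V	G637	MYH8	perinatal	Loop 2	9.2	N	310	0	-
actin_binding	2276282	E643K	K643	MYO7A	myosin VIIA	Loop 2	-	-	-	0	-
actin_binding	61743282	F655S	-	MYO7B	myosin VIIB	actin bind	-	-	-	0	-
nterm_u50_l50	3729993	D4A	-	MYH7	beta-cardiac	N-term	0	Y	525	0	-
nterm_u50_l50	34042358	D4E	-	MYH13	super-fast	N-term	3.2	?	62	0	-
nterm_u50_l50	45511396	R18C	-	MYH7	beta-cardiac	N-term	0.4	Y	0	0	zero_count
nterm_u50_l50	61730792	R24P/L	-	MYH1	2x	N-term	-	-	-	0	-
nterm_u50_l50	41312286	T25M	I25	MYH7B	beta-cardiac	N-term	-	-	-	0	-
nterm_u50_l50	590722	P(<32)T	-	MYH14	iso1/iso2	undefined	-	-	-	0	-
nterm_u50_l50	2404991	G(<48)S	-	MYO7B	myosin VIIB	undefined	-	-	-	0	-
nterm_u50_l50	1052030	L(<58)S	-	MYO7A	myosin VIIA	undefined	-	-	-	0	-
nterm_u50_l50	35218876	R(<64)Q	-	MYO9B	myosin IXB	undefined	2.5	?	39	0	-
nterm_u50_l50	10518970	P(<82)L	-	MYO9A	myosin IXA	undefined	4.3	?	1224	0	-
nterm_u50_l50	17855105	R(<82)K	-	MYO9A	myosin IXA	undefined	-	-	-	0	-
nterm_u50_l50	2929516	T(<82)I	-	MYO9A	myosin IXA	undefined	-	?	1122	0	discordant
nterm_u50_l50	34773557	M142I	A142	MYH14	iso1/iso2	N-term	2.8	?	70	0	-
nterm_u50_l50	6174305	R145G	G145	MYO10	myosin X	N-term	-	-	-	0	-
nterm_u50_l50	41298131	I148T	R148	MYO7A	myosin VIIA	N-term	-	-	-	0	-
nterm_u50_l50	58359270	L199F	I199	MYO9B	myosin IXB	N-term	-	-	-	0	-
nterm_u50_l50	28936391	H287R	-	MYO6	myosin VI	U50	-	-	-	0	-
nterm_u50_l50	6870170	E300D	L300	MYO10	myosin X	U50	1.3	?	908	0	-
nterm_u50_l50	35512085	T307P	-	MYH4	2b	U50	-	-	-	0	-
nterm_u50_l50	34498817	P320A	E320	MYH14	iso1/iso2	U50	5.5	?	309	0	-
nterm_u50_l50	35315400	S323C	V323	MYH14	iso1/iso2	U50	2.5	?	78	0	-
nterm_u50_l50	34124921	I326T	-	MYH8	perinatal	U50	1.2	N	39	0	-
nterm_u50_l50	35984286	Q329R	-	MYH4	2b	U50	2.5	N	39	1	-
nterm_u50_l50	34846075	V335I	T335	MYO10	myosin X	U50	2.5	?	39	0	-
nterm_u50_l50	41298135	R336H	D336	MYO7A	myosin VIIA	U50	-	-	-	0	-
nterm_u50_l50	34419805	T345A	-	MYH8	perinatal	U50	2.8	N	35	0	-
nterm_u50_l50	61756677	V350D/A	-	MYH2	2a	U50	-	-	-	0	-
nterm_u50_l50	11750538	R350W	V350	MYO10	myosin X	U50	50	?	1264	0	-
nterm_u50_l50	1724577	E389D	Y389	MYH12	myosin V	U50	17.2	Y	1262	0	-
nterm_u50_l50	61732664	Y(389-390)H	-	MYO6	myosin VI	U50	-	-	-	0	-
nterm_u50_l50	61742021	I514T	-	MYO7B	myosin VIIB	L50	-	-	-	1	-
nterm_u50_l50	12949680	A594T	-	MYH4	2b	L50	7.4	N	39	0	-
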