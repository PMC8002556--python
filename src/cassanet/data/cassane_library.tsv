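id	formula	observed_mz	rt_min	printed_delta_ppm	arm	substituents	generic_losses	ref_status	flag	dominant_group	abundance_profile
A1	C24H37NO5	420.2733	16.97	2.74	NME	ester60:1;oxo:1	hydroxy:1	known	-	Sua *	9/48/33/11
A2	C23H35NO5	406.2569	16.75	4.69	PAE	ester60:1	-	NEW	-	Sua *	21/71/4/4
A3	C24H35NO6	434.2549	14.54	2.74	NME	ester60:1;oxo:1	hydroxy:1	known	-	Ouesso-Sua	53/36/6/5
A4	C25H39NO5	434.2855	17.16	10.59	DME	ester60:1;oxo:1	-	known	-	Sua *	24/52/14/11
A5	C24H35NO6	434.2555	15.77	4.11	NME	ester60:1;oxo:1	hydroxy:1	known	-	ivo-Libr 2	9/11/28/53
B1	C26H39NO8	494.2757	14.44	1.74	NME	ester60:2;hydroxy:1	hydroxy:1;oxo:1	known	-	Sua *	10/82/3/5
B2	C24H37NO7	452.2664	12.62	4.7	NME	ester60:1;hydroxy:1	hydroxy:1;oxo:1	known	-	Ouesso-Sua	45/26/19/9
B3	C25H37NO8	480.2607	14.34	7.32	PAE	ester60:2;hydroxy:1	hydroxy:1;oxo:1	NEW	unverifiable-as-printed	Sua *	16/83/0/0
B4	C25H37NO8	480.2828	14.51	49	PAE	ester60:2;hydroxy:1	hydroxy:1;oxo:1	NEW	unverifiable-as-printed	Sua *	24/70/4/3
B5	C27H41NO8	508.2980	14.40	10.64	NME	ester60:2	hydroxy:1;oxo:1	known	unverifiable-as-printed	ivo-Libr 2	2/4/39/55
B6	C30H45NO8	548.3212	17.04	1.09	NME	ester60:1;tigloyl:1	oxo:1	NEW	-	ivo	0/0/48/52
B7	C30H47NO8	550.3350	17.28	4.45	NME	ester60:1;dihydrotigloyl:1	oxo:1	NEW	-	ivo	0/0/50/50
B8	C30H47NO9	566.3312	14.05	2.69	NME	ester60:1;hydroxytigloyl:1	oxo:1	NEW	unverifiable-as-printed	ivo	0/1/51/48
B9	C28H43NO7	506.3102	15.65	2.04	NME	hydroxytigloyl:1;oxo:1	-	NEW	-	ivo	0/0/52/48
B10	C28H41NO6	488.2988	17.87	3.83	NME	tigloyl:1;oxo:1	hydroxy:1	NEW	-	ivo-Libr 1	1/1/59/39
B11	C30H47NO9	566.3308	14.17	2.76	NME	ester60:1;hydroxytigloyl:1	oxo:1	NEW	-	ivo-Libr 2	1/1/3/95
B12	C31H49NO12	628.3323	10.40	0.72	NME	ester60:1;glucosyl:1	hydroxy:1;oxo:1	NEW	-	ivo-Libr 2	1/0/35/65
B13	C23H37NO4	392.2802	13.27	1.70	NME	hydroxy:1	hydroxy:1;oxo:1	NEW	-	ivo-Libr 1	4/7/63/27
B14	C23H37NO4	392.2789	12.66	1.62	NME	oxo:1	hydroxy:1;oxo:1	NEW	-	ivo-Libr 1	5/6/62/27
B15	C28H45NO6	492.3314	15.83	1.15	NME	hydroxytigloyl:1;oxo:1	hydroxy:1	known	-	ivo-Libr 1	1/3/53/43
B16	C27H43NO6	478.3067	15.61	20.1	PAE	hydroxytigloyl:1;oxo:1	hydroxy:1	NEW	unverifiable-as-printed	Sua *	21/61/7/11
B17	C22H35NO4	378.2625	13.10	3.67	PAE	hydroxy:1	hydroxy:1;oxo:1	NEW	-	Sua *	33/62/3/2
C1	C24H37NO7	452.2636	11.17	1.50	NME	ester60:1;hydroxy:1	hydroxy:1;oxo:1	known	-	Ouesso-Sua	60/36/1/3
C2	C23H35NO7	438.2501	10.97	3.36	PAE	ester60:1;hydroxy:1	hydroxy:1;oxo:1	NEW	-	Ouesso-Sua	60/40/0/0
C3	C25H39NO7	466.2787	11.31	2.64	DME	ester60:1;hydroxy:1	hydroxy:1;oxo:1	NEW	-	Ouesso-Sua	69/24/2/5
BS1	C24H35NO7	450.2477	12.84	1.27	NME	ester60:1;hydroxy:1	hydroxy:1;oxo:1	NEW	unverifiable-as-printed	Sua *	40/59/0/1
BS2	C28H43NO6	490.3145	18.48	3.71	NME	tigloyl:1;hydroxy:1	hydroxy:1;oxo:1	NEW	-	ivo-Libr 1	0/0/65/35
BS3	C28H43NO7	506.3102	15.65	2.04	NME	hydroxytigloyl:1;oxo:1	-	NEW	-	ivo	0/0/52/48
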