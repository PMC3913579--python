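mutant_id	position	locus	description	operon	ec	pearson	pct_od	TCA	GLU
P7A10	2361816	NCgl2147	Glutamate-ammonia-ligase adenylyltransferase	false	2.7.7.42	0.97	67	false	true
P7C5	2238004	NCgl2038	Hypothetical protein	false		0.96	107	false	true
P7C6				false		0.92	50	true	true
P7E1				false		0.92	91	false	true
P7F11	179131	NCgl0163	Major facilitator superfamily permease	true		0.97	83	true	true
P8A2	368514	NCgl0340	Nucleoside-diphosphate sugar epimerase	true		0.96	89	false	true
P8D4				false		0.93	42	true	false
P8F4	1042752	NCgl0944	Major facilitator superfamily permease	false		0.97	75	true	false
P8F10	2380663	NCgl2167	Pyruvate dehydrogenase subunit E1	false	1.2.4.1	0.96	48	true	true
P8F12	1142652	NCgl1051	Hypothetical protein	true		0.95	55	true	true
P8G3	1690962	NCgl1533	GTP cyclohydrolase II	true	3.5.4.25	0.94	40	true	true
P21D2	3119587	intergenic		false		0.98	81	true	false
P21E9	1525622	NCgl1392	Hypothetical protein	true		0.98	99	true	false
P21G4	2867647	NCgl2603	Cell division protein	false		0.98	87	true	false
P21G11	199693	NCgl0181	Glutamate synthase large subunit	true	1.4.1.13	0.98	119	true	false
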