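# clinical follow-up of the 59 tumors (status Death* = death of unknown
# cause, censored in the cause-specific analysis; analysis = which assays
# were run on the sample)
sample	histology	stage	age	treatment	followup_months	status	analysis
R035	SCC	IB2	48	TELE+CHEMO+HT	73	Alive	CN/EX
R062	SCC	IB2	42	TELE+CHEMO+HT	62	Alive	CN
R072	SCC	IB1	61	HT+TELE+BRACHY	86	Alive	CN/EX
R075	ACC	IB1	73	TELE+HT	58	Alive	CN/EX
R081	ACC	IB1	41	HT	62	Alive	EX
R102	SCC	IIB	66	TELE+CHEMO+HT	84	Alive	EX
R111	SCC	IB1	44	TELE+HT	78	Alive	CN
R116	SCC	IB1	30	HT	26	Death	CN
R121	SCC	IB1	35	HT	61	Alive	EX
R124	SCC	IB1	42	HT	62	Alive	EX
R154	SCC	IIIB	42	TELE+CHEMO	26	Death	CN/EX
R156	SCC	IIIB	70	TELE+BRACHY+CHEMOi+HT	6	Death	EX
R157	SCC	IVB	69	PALIATIVE CARE	2	Death	EX
R158	SCC	IVB	37	PALIATIVE CARE	12	Death	EX
R183	SCC	IB1	64	TELE+BRACHY	70	Alive	CN/EX
R189	ACC	IB1	47	HT	60	Alive	CN/EX
R194	SCC	IIA	64	UNTREATED	19	Death	CN/EX
R198	SCC	IVA	50	PALIATIVE CARE	10	Death	CN/EX
R208	SCC	IB1	46	TELE+BRACHY	23	Death	CN/EX
R221	SCC	IB2	41	TELE+BRACHY+CHEMO	33	Death*	CN/EX
R230	SCC	IB1	62	TELE+BRACHY	71	Alive	EX
R240	SCC	IIIB	31	TELE+BRACHY+CHEMO	11	Death	CN/EX
R244	SCC	IIB	52	TELE+HT	83	Alive	CN/EX
R248	SCC	IB1	36	TELE+BRACHY+HT	24	Death	CN
R260	SCC	IB2	24	TELE+CHEMO	66	Alive	CN/EX
R265	SCC	IB1	46	TELE+BRACHY	67	Alive	EX
R268	SCC	IIB	34	TELE+BRACHY+CHEMO	58	Alive	EX
R282	SCC	IIIB	41	TELE+BRACHY+CHEMO	70	Alive	CN/EX
R298	ASCC	IIIB	50	TELE+CHEMO+HT	48	Death	CN/EX
R311	SCC	IIIB	72	UNTREATED	1	Death	EX
R315	SCC	IIIB	41	TELE+BRACHY+CHEMO	10	Death	EX
R322	SCC	IIIB	74	TELE+BRACHY	60	Alive	CN/EX
R324	SCC	IB2	28	TELE+BRACHY+CHEMO	14	Death	EX
R330	SCC	IB1	72	TELE+BRACHY	54	Alive	EX
R336	SCC	IB2	36	TELE+BRACHY+CHEMO	64	Alive	EX
R339	SCC	IB2	31	TELE+BRACHY+CHEMO	13	Death	EX
R365	SCC	IIIB	38	TELE+CHEMO	6	Death	CN/EX
R368	SCC	IIIB	36	TELE+BRACHY+CHEMOi	70	Alive	EX
R369	SCC	IB1	50	HT	65	Alive	CN/EX
R378	SCC	IB2	42	TELE+BRACHY+CHEMO	56	Alive	EX
R380	SCC	IIIB	64	UNTREATED	12	Death	CN/EX
R386	SCC	IB1	73	TELE+BRACHY	70	Alive	CN/EX
R390	SCC	IB1	51	TELE+BRACHY+CHEMOi	64	Alive	EX
R392	SCC	IIIB	69	TELE+BRACHY	61	Alive	CN/EX
R409	SCC	IB2	68	TELE+BRACHY+CHEMO	42	Alive	EX
R411	SCC	IB1	34	HT+TELE+BRACHY	60	Alive	EX
R412	SCC	IB2	33	TELE+BRACHY+CHEMO	63	Alive	EX
R426	SCC	IIB	67	TELE+BRACHY+CHEMO	23	Death	EX
R444	SCC	IIB	71	UNTREATED	26	Death	CN/EX
R455	SCC	IIA	67	TELE+BRACHY	60	Alive	EX
R457	SCC	IIIB	60	TELE+BRACHY	15	Death	EX
R476	SCC	IB1	41	HT	68	Alive	CN/EX
R478	SCC	IB1	46	TELE+BRACHY	60	Alive	CN/EX
R483	SCC	IVB	51	PALIATIVE CARE	11	Death	CN/EX
R486	SCC	IB1	39	TELE+HT	33	Alive	EX
R489	SCC	IIIB	43	TELE+BRACHY	37	Alive	EX
R494	SCC	IIIB	55	TELE+CHEMO+BRACHYi	6	Death	CN/EX
R495	SCC	IIB	68	TELE+BRACHY	62	Alive	EX
R496	SCC	IIIB	52	TELE+BRACHY+CHEMO	63	Alive	CN/EX
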