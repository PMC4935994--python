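family	superfamily	monomer_length	at_content	n_variants	abundance_sl	abundance_nl	divergence_sl	divergence_nl	n_contigs	mnrpc	L1	L2	X	M3	M4	M5	M6	M7	M8	S9	S10	S11	pattern	in_working_set	note
LmiSat01-193	1.0	193	59.59	5	0.98225	0.6903	4.67	5.07	332	15	p	p	p	p	p	p	p	p	p	p	p	p	c	True	
LmiSat02-176		176	53.41	1	0.47509	0.9996	5.32	5.38	12931	100			p			p		p		p	p	p	c	True	
LmiSat03-195		195	58.97	6	0.29481	0.2305	5.42	5.96	1003	206	p			p									c	True	
LmiSat04-18		18	50.0	2	0.06194	0.0816	7.2	7.23	108	156										i,d		i	c	True	
LmiSat05-400		400	51.25	1	0.05431	0.0483	4.65	5.04	91	3										i,d		p	c	True	
LmiSat06-185		185	59.46	4	0.0541	0.07	4.76	5.28	274	42		p		p					p	p		p	c	True	
LmiSat07-5-tel		5	60.0	1	0.04438	0.1611	1.75	6.12	57	2868	t	t	t	t	t	t	t	t	t	t	t	t	c	False	telomeric repeat, known function
LmiSat08-168		168	57.74	1	0.03737	0.0467	4.96	4.91	327	28			p										m	True	
LmiSat09-181		181	60.22	5	0.02944	0.0072	5.38	7.42	45	60									p				c	True	
LmiSat10-9		9	55.56	2	0.02269	0.029	11.79	11.42	267	243										p		p	c	True	
LmiSat11-37		37	62.16	7	0.01873	0.0069	7.75	8.12	317	106				p									c	True	
LmiSat12-273	2.0	273	56.41	3	0.01836	0.0113	3.5	5.29	23	16		d											c	True	
LmiSat13-259	1.0	259	57.53	5	0.01697	0.0115	4.38	6.25	137	27					p								c	True	
LmiSat14-216		216	51.85	4	0.01426	0.0091	5.39	8.79	70	40				i,i								i	c	True	
LmiSat15-190		190	55.26	1	0.01426	0.0166	4.09	4.5	212	9								p					c	True	
LmiSat16-278	2.0	278	62.59	1	0.0139	0.0082	2.49	3.01	17	9		d											c	True	
LmiSat17-75		75	57.33	1	0.01177	0.0033	5.79	6.66	112	7				p									c	True	
LmiSat18-210		210	60.48	1	0.01121	0.0267	6.33	4.59	6	2								p					c	True	
LmiSat19-89		89	60.67	1	0.01058	0.0034	3.82	6.44	10	4		p											c	True	
LmiSat20-15		15	53.33	1	0.01032	0.0201	12.71	14.15	190	256													nc	True	
LmiSat21-38		38	50.0	1	0.01013	0.0019	2.85	2.91	7	20										i,d			m	True	
LmiSat22-17		17	58.82	1	0.01	0.0092	10.81	10.28	182	426								i					c	True	
LmiSat23-223		223	61.43	1	0.00927	0.0106	4.42	5.73	18	10		d					d			i			c	True	
LmiSat24-266	3.0	266	56.39	1	0.00895	0.0066	2.06	5.14	51	4													nc	True	
LmiSat25-219		219	39.73	2	0.00834	0.0105	5.88	8.2	21	5		d											c	True	
LmiSat26-240	4.0	240	66.2	2	0.00809	0.00436	7.44	9.25	33	8												i	c	True	
LmiSat27-57		57	47.37	1	0.0079	0.0103	8.99	9.66	333	326													nc	True	
LmiSat28-263	3.0	263	57.41	2	0.00768	0.0139	1.79	2.22	91	12		i,i											c	True	
LmiSat29-68		68	58.82	1	0.00719	0.0019	9.36	14.48	46	89				p									c	True	
LmiSat30-138		138	40.58	1	0.0068	0.0055	5.74	9.03	8	2									p				c	True	
LmiSat31-8	5.0	8	50.0	3	0.00668		3.86		23	83										p	p		c	True	
LmiSat32-261		261	51.72	1	0.00631	0.0056	5.98	9.18	37	12		d											c	True	
LmiSat33-21		21	47.62	1	0.00627	0.0039	7.77	8.35	30	179										i			c	True	
LmiSat34-299		299	61.87	1	0.00622	0.0048	6.81	7.39	406	3		p											c	True	
LmiSat35-228		228	55.7	1	0.00597	0.0053	2.43	4.64	25	18													nc	True	
LmiSat36-15		15	60.0	2	0.00585	0.0093	16.88	15.12	279	302													nc	True	
LmiSat37-238	4.0	238	66.0	1	0.00544	0.00224	6.53	6.52	111	37	i											p	c	True	
LmiSat38-42		42	64.29	1	0.00511	0.0046	14.56	14.94	106	692												i	c	True	
LmiSat39-53		53	32.08	1	0.00503	0.0013	6.79	9.17	14	119										i			c	True	
LmiSat40-148		148	67.57	1	0.00459	0.0023	2.35	3.05	20	4										d			c	True	
LmiSat41-180		180	61.67	1	0.00455	0.0058	3.38	2.14	4	6									i				c	True	
LmiSat42-127		127	51.18	1	0.00447	0.0012	2.02	4.6	2	2						p							c	True	
LmiSat43-231	3.0	231	53.68	1	0.0044		0.68		44	3									i				m	True	
LmiSat44-17		17	29.41	1	0.00428	0.0005	11.45	11.3	7	53										i			c	True	
LmiSat45-274	3.0	274	54.01	1	0.0042	0.0066	8.2	7.22	152	12	p,i		p	p									c	True	
LmiSat46-353		353	59.77	1	0.00407	0.0071	15.49	11.38	1799	2													none	False	not PCR-confirmed
LmiSat47-41		41	41.46	1	0.00369	0.0058	12.46	13.22	48	394					p								c	True	
LmiSat48-220		220	58.18	1	0.00366	0.0011	3.8	7.74	18	3													nc	True	
LmiSat49-47		47	42.55	1	0.00362	0.0113	6.24	6.7	127	282				p									c	True	
LmiSat50-16	5.0	16	56.25	2	0.00331	0.0169	8.31	8.24	54	64										i			c	True	
LmiSat51-241	4.0	241	63.9	1	0.00294	0.0058	7.32	3.97	33	138		i											c	True	
LmiSat52-143		143	51.75	1	0.00257	0.0076	22.15	14.01	1796	3													none	False	not PCR-confirmed
LmiSat53-47		47	40.43	1	0.00248	0.019	3.16	5.2	9	23										i			c	True	
LmiSat54-272	3.0	272	56.25	1	0.00244	0.0051	4.55	4.15	164	51			p	i			i	p	d				m	True	
LmiSat55-90		90	35.56	1	0.00164	0.0074	15.62	8.57	4	3													nc	True	
LmiSat56-19		19	52.63	4	0.00083	0.0067	5.09	4.31	15	97							p			i			m	True	
LmiSat57-230		230	63.04	1	0.00052	0.0047	18.21	3.4	212	25													none	False	not PCR-confirmed
LmiSat58-86		86	41.86	1	8e-05	0.0127	5.99	3.12	10	4													nc	True	
LmiSat59-16	5.0	16	43.75	3	4e-05	0.0049	18.23	14.54	13	13													nc	True	
LmiSat60-255		255	52.94	1	4e-05	0.0053	1.03	0.99	0	0													nc	True	
LmiSat61-63		63	42.86	1	2e-05	0.0062	14.99	4.6	1	11													nc	True	
LmiSat62-23		23	43.48	1		0.0045		4.57	1	9								p					c	True	
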