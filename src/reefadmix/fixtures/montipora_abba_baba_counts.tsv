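id	p1	p2	p3	outgroup	n_abba	n_baba	d_printed	p_printed	direction_printed
H1	R6Mdil	Mflab	Mdil12	L27incra	247	286	-0.073	0.091	none
H2	R6Mdil	L26turg	Mdil12	L27incra	151	237	-0.222	1.3E-05	13
H3	R6Mdil	R19turg	Mdil12	L27incra	102	195	-0.313	6.8E-08	13
H4	L26turg	R19turg	Mdil12	L27incra	71	122	-0.264	2.4E-04	13
H5	Mflab	R19turg	Mdil12	L27incra	99	204	-0.347	1.6E-09	13
H6	Mflab	L26turg	Mdil12	L27incra	159	221	-0.163	1.5E-03	13
H7	Mdil12	Mflab	R6Mdil	L27incra	192	286	-0.197	1.7E-05	13
H8	Mdil12	L26turg	R6Mdil	L27incra	112	237	-0.358	2.2E-11	13
H9	Mdil12	R19turg	R6Mdil	L27incra	82	195	-0.408	1.1E-11	13
H10	L26turg	Mflab	R6Mdil	L27incra	182	166	0.046	0.391	none
H11	L26turg	R19turg	R6Mdil	L27incra	78	125	-0.232	0.001	13
H12	Mflab	R19turg	R6Mdil	L27incra	109	202	-0.299	0.000	13
H13	Mdil12	R6Mdil	Mflab	L27incra	192	247	-0.125	0.009	13
H14	Mdil12	R19turg	Mflab	L27incra	86	204	-0.407	0.000	13
H15	Mdil12	L26turg	Mflab	L27incra	134	221	-0.245	0.000	13
H16	R6Mdil	L26turg	Mflab	L27incra	166	182	-0.046	0.391	none
H17	R6Mdil	R19turg	Mflab	L27incra	112	202	-0.287	0.000	13
H18	L26turg	R19turg	Mflab	L27incra	70	115	-0.243	0.001	13
H19	Mdil12	R6Mdil	R19turg	L27incra	82	102	-0.109	0.140	none
H20	Mdil12	L26turg	R19turg	L27incra	84	71	0.084	0.296	none
H21	Mdil12	Mflab	R19turg	L27incra	86	99	-0.070	0.339	none
H22	R6Mdil	Mflab	R19turg	L27incra	112	109	0.014	0.840	none
H23	R6Mdil	L26turg	R19turg	L27incra	92	78	0.082	0.283	none
H24	L26turg	Mflab	R19turg	L27incra	70	85	-0.097	0.228	none
H25	Mdil12	R6Mdil	L26turg	L27incra	112	151	-0.148	0.016	none
H26	Mdil12	R19turg	L26turg	L27incra	84	122	-0.184	0.008	13
H27	Mdil12	Mflab	L26turg	L27incra	134	159	-0.085	0.144	none
H28	R6Mdil	Mflab	L26turg	L27incra	166	166	0.000	1.000	none
H29	R6Mdil	R19turg	L26turg	L27incra	92	125	-0.152	0.025	none
H30	R19turg	Mflab	L26turg	L27incra	115	85	0.150	0.034	none
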