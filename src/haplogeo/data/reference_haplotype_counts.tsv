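haplotype	SZS	HN	GLS	XD	YKBLG	TST	MSG	BLG
H01	0	0	1	0	0	0	0	0
H02	0	0	8	0	0	0	0	0
H03	0	1	0	0	0	0	0	0
H04	0	1	0	0	0	0	0	0
H05	0	1	0	0	0	0	0	0
H06	0	1	0	0	0	0	0	0
H07	0	1	0	0	0	0	0	0
H08	0	1	0	0	0	0	0	0
H09	0	0	0	0	0	1	0	0
H10	0	0	0	0	0	2	0	0
H11	0	1	0	0	0	6	0	0
H12	0	0	0	0	0	1	0	0
H13	0	1	0	0	0	0	0	0
H14	0	1	0	0	0	0	0	0
H15	0	1	0	0	0	0	0	0
H16	0	0	0	2	0	0	0	0
H17	0	0	0	2	0	0	0	0
H18	0	0	0	2	0	0	0	0
H19	0	0	0	1	0	0	0	0
H20	0	0	0	0	0	0	4	0
H21	0	0	0	0	0	0	1	0
H22	0	0	0	0	0	0	4	0
H23	0	0	0	0	0	0	1	0
H24	0	0	0	0	0	0	0	1
H25	0	0	0	0	0	0	0	4
H26	0	0	0	0	0	0	0	1
H27	0	0	0	0	0	0	0	1
H28	0	0	0	0	0	0	0	1
H29	0	0	0	0	0	0	0	1
H30	0	0	0	0	8	0	0	0
H31	0	0	0	1	0	0	0	0
H32	0	0	0	1	0	0	0	0
H33	0	0	0	1	0	0	0	0
H34	5	0	0	0	0	0	0	0
H35	1	0	0	0	0	0	0	0
H36	2	0	0	0	0	0	0	0
H37	2	0	0	0	0	0	0	0
H38	0	0	1	0	0	0	0	0
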