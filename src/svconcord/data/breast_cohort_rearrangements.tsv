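patient	sample	paired_sample	total	shared	specific	cn_shared_pct
P3	P	M1	216	212	4	44
P3	M1	P	224	212	12
P3	P	M2	202	195	7	40
P3	M2	P	212	195	17
P3	M1	M2	224	217	7	43
P3	M2	M1	229	217	12
P6	P	M	163	162	1	42
P6	M	P	165	162	3
P7	P	M	78	62	16	16
P7	M	P	82	62	20
P8	P	M	52	36	16	25
P8	M	P	59	36	23
P12	P	M1	38	29	9	28
P12	M1	P	43	29	14
P12	P	M2	40	30	10	29
P12	M2	P	39	30	9
P12	M1	M2	38	35	3	36
P12	M2	M1	39	35	4
P14	P	M	54	50	4	33
P14	M	P	56	50	6
P15	P	M	26	16	10	27
P15	M	P	18	16	2
P16	P	M	100	99	1	24
P16	M	P	117	99	18
P17	P	M	82	82	0	40
P17	M	P	87	82	5
P18	P	M	310	269	41	35
P18	M	P	404	269	135
P20	P	M	212	174	38	36
P20	M	P	221	174	47
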