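primer_id	primer_type	tnb	npb
UBC812	ISSR	13	12
UBC827	ISSR	10	10
UBC828	ISSR	9	8
UBC829	ISSR	12	10
UBC830	ISSR	14	13
UBC835	ISSR	15	13
UBC836	ISSR	17	14
UBC844	ISSR	14	12
UBC848	ISSR	14	13
UBC854	ISSR	15	15
UBC868	ISSR	13	12
UBC876	ISSR	16	13
UBC879	ISSR	17	14
UBC887	ISSR	14	14
UBC890	ISSR	13	11
UBC891	ISSR	14	12
SCoT2	SCoT	17	14
SCoT3	SCoT	34	31
SCoT4	SCoT	21	19
SCoT5	SCoT	21	19
SCoT6	SCoT	22	20
SCoT7	SCoT	22	20
SCoT9	SCoT	20	19
SCoT10	SCoT	21	20
SCoT12	SCoT	25	24
SCoT13	SCoT	25	22
SCoT15	SCoT	18	16
SCoT16	SCoT	26	24
SCoT18	SCoT	20	18
SCoT21	SCoT	21	19
SCoT28	SCoT	25	22
SCoT31	SCoT	22	19
SCoT34	SCoT	21	19
SCoT35	SCoT	21	19
SCoT37	SCoT	23	20
SCoT48	SCoT	20	18
cnl35	EST-SSR	9	8
cnl37	EST-SSR	10	9
cnl42	EST-SSR	9	8
cnl47	EST-SSR	9	8
cnl51	EST-SSR	8	6
cnl55	EST-SSR	14	11
cnl61	EST-SSR	5	4
cnl86	EST-SSR	11	8
cnl100	EST-SSR	5	4
cnl115	EST-SSR	7	6
cnl119	EST-SSR	6	6
cnl130	EST-SSR	7	6
cnl144	EST-SSR	10	10
cnl147	EST-SSR	9	7
cnl158	EST-SSR	9	9
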