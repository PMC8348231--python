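wt	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	0	20	37	30	27	32	29	35	25	34	11	30	43	35	40	29	28	35	17	27
C	16	0	2	5	1	1	5	5	6	5	4	4	6	3	2	11	2	1	1	3
D	23	22	0	28	26	19	16	25	23	30	10	29	33	20	33	29	27	14	18	13
E	29	21	29	0	18	25	10	20	22	25	13	18	24	18	19	23	21	19	22	17
F	30	11	16	9	0	17	15	6	10	6	2	13	20	14	18	7	18	6	11	8
G	29	16	25	23	22	0	27	27	16	33	9	18	38	17	31	23	30	12	20	22
H	13	5	7	3	8	8	0	11	6	6	5	7	10	10	6	11	11	10	6	10
I	38	19	35	29	11	33	31	0	27	17	15	20	39	30	36	36	22	26	19	23
K	26	8	18	29	12	18	18	10	0	15	9	14	24	18	23	18	14	17	6	8
L	47	33	35	44	21	41	36	26	41	0	30	37	25	23	34	59	49	28	21	29
M	15	13	13	11	9	12	14	14	8	21	0	16	15	17	10	12	5	10	9	9
N	10	11	13	14	9	14	9	7	9	10	6	0	16	8	9	7	10	10	7	6
P	14	11	12	14	7	17	21	10	7	11	7	6	0	8	11	14	9	21	8	8
Q	14	12	14	11	9	12	12	8	14	12	4	11	15	0	14	18	15	14	5	11
R	26	21	25	21	22	22	27	18	17	23	11	21	26	29	0	28	28	28	17	14
S	18	8	13	9	11	15	7	6	6	9	4	11	8	9	16	0	15	10	9	11
T	26	13	17	20	15	25	17	12	12	22	21	24	25	17	22	32	0	20	11	13
V	17	19	21	18	13	19	25	25	24	23	15	22	32	19	33	42	26	0	14	15
W	9	5	3	9	6	4	1	2	7	4	3	2	6	4	5	6	5	5	0	2
Y	14	7	11	13	13	15	11	9	11	14	6	6	15	7	15	9	10	12	2	0
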