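lg	n_markers	n_contigs	length_cm
LG1	30	21	92.1
LG2	39	35	89.2
LG3	21	15	82.3
LG4	32	17	75.5
LG5	15	10	74.8
LG6	28	25	73.9
LG7	12	9	62.8
LG8	17	15	54.2
LG9	15	9	53.5
LG10	18	14	52
LG11	27	17	51.7
LG12	14	10	45.5
LG13	10	10	45.1
LG14	14	11	41.6
LG15	16	13	37.4
LG16	8	4	35.7
LG17	9	6	32
LG18	16	10	30.7
LG19	4	3	26.9
LG20	7	3	26.8
LG21	6	6	21.9
LG22	6	5	21.5
LG23	14	13	18.8
LG24	6	5	18.1
LG25	6	5	17.5
LG26	4	3	11
LG27	8	5	9.2
LG28	2	2	9
LG29	2	2	7
LG30	2	2	7
LG31	3	3	6.1
LG32	2	2	3
LG33	3	2	0
LG34	4	4	0
LG35	4	3	0
LG36	3	3	0
LG37	2	2	0
LG38	2	2	0
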