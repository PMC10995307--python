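phylum	人參	升麻	枳實	牛膝	甘草	當歸	知母	附子
大腸腑門	27	13	23	7	83	49	1	33
小腸腑門	1	3	2	4	8	9	1	6
心臟門	103	20	5	6	103	39	12	22
癰疽門	76	74	15	13	223	149	39	53
肝臟門	3	13	18	28	56	43	3	30
肺臟門	76	18	9	3	110	12	16	22
胃腑門	61	5	3	1	62	17	3	29
脾臟門	141	27	40	9	208	72	11	98
腎臟門	50	4	10	59	59	57	2	86
膀胱腑門	6	2	2	4	9	5	2	10
膽腑門	24	5	2	1	18	1	4	1
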