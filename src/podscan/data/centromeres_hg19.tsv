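chrom	p_end	q_start
1	121500000	124600000
2	92300000	95300000
3	90500000	93500000
4	49700000	52700000
5	46400000	49400000
6	58800000	61800000
7	58100000	61100000
8	43800000	46800000
9	47400000	50400000
10	39300000	42300000
11	51600000	54700000
12	34900000	37900000
13	16000000	19000000
14	16100000	19100000
15	15800000	20700000
16	35300000	38300000
17	22300000	25300000
18	15500000	18500000
19	24600000	27700000
20	26400000	29400000
21	11300000	14300000
22	13000000	16000000
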