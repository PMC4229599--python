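fermentation_id	nacl_mM	start_pH	temperature_C	aeration	od_final	mu_max
1	0	6.0	27	+	1.95	0.73
2	100	6.5	27	+	2.68	0.73
3	0	6.5	27	-	3.04	0.94
4	100	6.0	27	-	1.76	0.83
5	0	6.0	30	-	2.18	1.06
6	100	6.5	30	-	2.72	1.01
7	0	6.5	30	+	3.28	0.95
8	100	6.0	30	+	2.05	0.82
9	0	6.0	35	+	2.37	1.01
10	100	6.5	35	+	3.17	0.98
11	0	6.5	35	-	3.06	1.21
12	100	6.0	35	-	2.02	1.09
13	100	6.5	30	-	2.78	1.00
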