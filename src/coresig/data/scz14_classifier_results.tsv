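cohort_id	cr_srvs	cr_anova	cr_pool	n_srvs	n_anova	n_pool	p_srvs	p_anova	p_pool
GSE12649	89.86	75.36	59.42	14	11	1276	<2.00e-4	<2.00e-4	0.12
GSE12654	92.86	89.29	60.71	16	310	1112	<2.00e-4	<2.00e-4	0.45
GSE12679	85.19	100	66.67	30	52	1440	<2.00e-4	<2.00e-4	0.07
GSE17612	90.20	88.24	52.94	30	60	1440	<2.00e-4	<2.00e-4	0.17
GSE21138	86.44	74.58	66.10	31	19	802	<2.00e-4	2.80e-3	0.64
GSE21935	88.10	85.71	64.29	67	527	1440	<2.00e-4	<2.00e-4	2.52e-2
GSE26927	93.85	89.23	69.23	64	40	1392	<2.00e-4	1.60e-3	0.93
GSE35974	89.36	84.04	64.89	28	14	1469	<2.00e-4	<2.00e-4	0.92
GSE35977	82.18	77.23	71.29	290	107	1469	<2.00e-4	2.00e-4	5.00e-3
GSE35978	53.38	71.28	52.31	27	17	1469	8.06e-2	<2.00e-4	0.24
GSE53987	55.34	68.93	52.43	5	82	1440	<4.80e-3	4.00e-4	1.00
GSE62191	79.66	76.27	54.24	44	11	693	<2.00e-4	<2.00e-4	0.48
GSE87610	90.51	86.13	74.45	517	238	1406	<2.00e-4	<2.00e-4	0.02
GSE93987	87.28	86.71	75.72	10	89	1429	<2.00e-4	<2.00e-4	0.65
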