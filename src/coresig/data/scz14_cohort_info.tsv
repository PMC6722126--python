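cohort_id	n_cases	n_controls	n_pool_genes	brain_region	ethnicity
GSE12649	35	34	1276	prefrontal cortex	Japan
GSE12654	13	15	1112	prefrontal cortex	Japan
GSE12679	16	11	1440	dorsolateral prefrontal cortex	United Kingdom
GSE17612	28	23	1440	BA10	United Kingdom
GSE21138	30	29	802	prefrontal cortex	USA
GSE21935	23	19	1440	BA22	United Kingdom
GSE26927	10	55	1392	Multiple Brodmann areas	United Kingdom
GSE35974	44	50	1469	parietal cortex	China
GSE35977	51	50	1469	parietal cortex	China
GSE35978	95	100	1469	parietal cortex	China
GSE53987	48	55	1440	prefrontal cortex (BA46)	USA
GSE62191	29	30	693	frontal cortex	Brazil
GSE87610	65	72	1406	prefrontal cortex	USA
GSE93987	67	106	1429	prefrontal cortex	USA
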