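gene	beta_geo	beta_sd	alpha_geo	alpha_sd	pancreas_geo	pancreas_sd	brain_geo	brain_sd	duodenum_geo	duodenum_sd	liver_geo	liver_sd	wat_geo	wat_sd	muscle_geo	muscle_sd	wbc_geo	wbc_sd
INS2	20576	914	413	63	636	26	0.0	0.0	0.2	0.0	nd		nd		nd		nd
IAPP	999	56	134	25	56.8	4	nd		nd		nd		nd		nd		nd
SLC2A2	143.7	8.5	11.1	1.7	nd		0.0	0.0	5.0	0.1	1.8	0.1	nd		nd		nd
PTPRN	137.1	8.7	98.0	18.2	4.5	0.2	18.2	3.0	0.0	0.0	0.0	0.0	0.1	0.1	0.4	0.1	0.0	0.0
CPE	133.1	5.3	46.4	6.4	12.6	1.1	27.2	1.1	0.9	0.0	nd		nd		5.9	1.3	0.0	0.0
PCSK1	26.1	1.2	8.1	5.1	nd		0.3	0.0	0.1	0.0	nd		nd		nd		0.1	0.1
SCG5	22.8	0.9	25.4	5.9	2.5	0.2	5.6	0.1	0.0	0.0	nd		nd		nd		nd
PPP1R1A	17.9	0.6	1.3	0.5	2.0	0.1	1.9	0.2	0.0	0.0	nd		nd		12.0	4.5	nd
DCX	14.6	0.4	2.4	0.3	0.4	0.1	0.7	0.1	0.0	0.0	0.0	0.0	nd		nd		nd
HYOU1	9.2	0.2	1.3	0.6	6.3	0.1	0.7	0.0	0.3	0.0	5.1	0.2	8.5	13.7	2.6	0.3	2.1	1.7
FOSB	8.4	1.4	3.3	1.4	nd		0.3	0.1	0.0	0.0	nd		nd		nd		nd
DDC	7.1	0.6	2.5	0.6	1.5	0.1	0.3	0.0	2.4	0.2	1.5	0.1	nd		0.1	0.0	0.0	0.0
PDX1	5.8	0.5	0.5	0.2	2.0	0.2	nd		0.0	0.0	0.0	0.0	nd		nd		nd
HADHSC	4.8	0.2	0.6	0.1	1.1	0.1	0.1	0.0	0.7	0.0	0.8	0.0	0.2	0.2	1.0	0.1	0.1	0.1
WNT4	3.7	0.1	1.0	0.8	0.4	0.0	0.1	0.0	0.0	0.0	0.1	0.0	1.2	1.2	5.1	0.8	0.0	0.0
SCG2	3.6	0.2	1.7	1.1	0.2	0.0	0.2	0.0	0.0	0.0	nd		nd		nd		nd
ST18	3.5	0.2	nd		nd		0.0	0.0	nd		nd		nd		nd		nd
SYTL4	3.3	0.1	0.9	0.6	0.3	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.3	0.3	0.1	0.0	0.0	0.0
ARMET	3.0	0.1	0.4	0.3	3.0	0.4	0.2	0.0	0.3	0.0	0.5	0.0	nd		0.3	0.0	0.2	0.1
GPSM1	2.5	0.1	0.5	0.1	0.1	0.0	0.4	0.0	0.0	0.0	0.0	0.0	0.2	0.2	0.1	0.0	0.1	0.1
GAD2	2.1	0.2	0.0	0.0	0.1	0.0	5.3	0.1	0.0	0.0	nd		nd		nd		nd
NNAT	1.0	0.0	0.5	0.2	0.1	0.0	5.5	0.4	0.0	0.0	0.0	0.0	0.0	0.0	0.4	0.1	nd
NEUROD1	0.7	0.0	0.0	0.0	0.1	0.0	0.0	0.0	0.0	0.0	nd		nd		nd		nd
GCK	0.6	0.0	0.8	0.1	0.1	0.0	0.0	0.0	0.0	0.0	0.2	0.0	nd		nd		nd
NPY	0.6	0.0	0.0	0.0	nd		0.9	0.1	0.0	0.0	0.0	0.0	nd		nd		nd
DDIT3	0.5	0.0	0.4	0.1	0.1	0.0	0.1	0.0	0.1	0.0	0.0	0.0	nd		0.2	0.1	0.2	0.1
NKX2-2	0.2	0.0	nd		0.1	0.0	0.0	0.0	0.0	0.0	nd		nd		nd		nd
GCG	46	1.5	2711	601	170	6.6	0.0	0.0	0.4	0.0	nd		nd		0.1	0.0	nd
CTRB1	341	17.0	304	48	30043	1145	0.0	0.0	2.3	0.0	0.0	0.0	nd		nd		0.1	0.1
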