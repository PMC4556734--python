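measure	group	mean	sd	n
age	ASC	15.05	1.9	14
age	SIB	15.11	2.0	14
age	CON	15.1	1.8	14
full_scale_iq	ASC	104.79	14.6	14
full_scale_iq	SIB	112.43	11.4	14
full_scale_iq	CON	113.43	9.1	14
verbal_iq	ASC	103.5	18.5	14
verbal_iq	SIB	110	12	14
verbal_iq	CON	110.5	6.9	14
performance_iq	ASC	106.1	16.8	14
performance_iq	SIB	110	11.5	14
performance_iq	CON	113.3	10.4	14
aq	ASC	39.14	7.2	14
aq	SIB	10.79	6.3	14
aq	CON	8.86	5.6	14
srs	ASC	112.9	38.2	14
srs	SIB	18.4	15.2	14
srs	CON	14.7	10.4	14
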