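gene	chrom	peak_start	atac_log2fc	atac_adj_p	bru_log2fc	bru_adj_p	concordance
Stab2	10	86471533	3.87	1.34e-03	12.93	3.45e-26	Yes
Stab2	10	86470475	3.15	1.06e-05	12.93	3.45e-26	Yes
Pax2	19	44830636	1.09	6.01e-06	8.32	5.73e-11	Yes
Pax2	19	44829214	1.63	6.87e-03	8.32	5.73e-11	Yes
Pax2	19	44830054	1.47	4.19e-03	8.32	5.73e-11	Yes
Tbx3	5	120120208	3.08	3.81e-12	17.48	6.68e-28	Yes
Lhx4	1	157589145	0.62	1.23e-02	7.41	3.07e-08	Yes
Zdbf2	1	63319600	3.01	2.40e-02	7.36	1.80e-21	Yes
Pax8	2	24301469	-3.19	1.57e-02	6.00	6.91e-244	No
Grin2b	6	136123298	1.41	1.11e-06	5.20	0.00e+00	Yes
Nkx6-1	5	102093567	3.52	2.85e-178	1.70	8.59e-29	Yes
Zic5	14	122863053	-2.93	4.23e-100	-2.38	1.67e-06	Yes
Map10	8	128193658	-2.06	3.04e-02	-6.86	4.80e-07	Yes
Eef1a2	2	180892656	-1.99	1.69e-02	-7.03	1.00e-06	Yes
Clec12b	6	129334486	-3.03	1.20e-39	-7.08	6.61e-07	Yes
Hoxc4	15	102864898	-2.80	7.89e-29	-7.18	7.74e-08	Yes
Pax3	17	8192985	-3.77	2.97e-66	-7.31	5.81e-16	Yes
Pitx2	3	128902161	-0.91	9.44e-03	-9.15	3.97e-13	Yes
Mab21l1	3	55586203	-6.61	4.50e-16	-9.87	4.29e-15	Yes
Stmn2	3	8509214	-2.96	1.54e-08	-10.52	3.57e-17	Yes
Phox2b	5	67489831	-6.14	2.11e-101	-11.03	7.30e-19	Yes
Tfap2b	1	19198995	-6.53	9.69e-26	-12.31	1.27e-23	Yes
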