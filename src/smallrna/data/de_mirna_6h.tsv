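gene	mean_medium	mean_lps	log2fc	direction	pvalue	padj
hsa-mir-155	5408.70	56381.00	3.50	up	5.47e-40	5.94e-37
hsa-mir-9-2	123.00	594.00	2.22	up	2.85e-11	1.54e-08
hsa-mir-146a	790.30	3770.80	2.10	up	6.01e-09	2.17e-06
hsa-mir-3665	617.60	1483.40	1.40	up	6.48e-06	0.001205
hsa-mir-7108	46.29	94.00	1.80	up	6.66e-06	0.001205
hsa-mir-9-1	2.43	14.25	2.88	up	5.50e-06	0.001205
hsa-mir-193a	610.90	966.00	0.76	up	9.33e-06	0.001446
hsa-mir-365b	23.14	58.13	1.46	up	3.14e-05	0.004258
hsa-mir-4674	110.70	296.10	1.74	up	3.91e-05	0.004709
hsa-mir-3960	349.40	686.80	1.08	up	4.36e-05	0.004734
hsa-mir-147b	66.92	234.60	2.29	up	9.94e-05	0.009809
hsa-mir-3196	71.71	211.20	1.74	up	0.000226	0.020391
hsa-mir-449c	15.14	29.50	1.27	up	0.000287	0.023971
hsa-mir-4508	71.29	138.90	1.14	up	0.000337	0.026131
hsa-mir-31	76.29	170.60	1.20	up	0.000469	0.03393
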