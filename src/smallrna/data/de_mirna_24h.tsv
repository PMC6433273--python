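gene	mean_medium	mean_lps	log2fc	direction	pvalue	padj
hsa-mir-187	9.30	534.00	5.792	up	8.82e-32	5.38e-29
hsa-mir-155	9835.00	85073.00	3.206	up	5.95e-22	1.82e-19
hsa-mir-9-2	56.00	582.00	3.207	up	1.96e-14	4.00e-12
hsa-mir-210	69.70	709.70	2.870	up	8.19e-10	1.25e-07
hsa-mir-146a	995.70	7594.00	2.877	up	1.51e-08	1.85e-06
hsa-mir-365b	39.70	137.00	2.092	up	3.42e-06	0.000348
hsa-mir-4284	184.70	460.00	1.569	up	2.18e-05	0.001902
hsa-mir-147b	76.30	420.70	2.453	up	3.29e-05	0.002511
hsa-let-7e	706.70	1660.70	1.409	up	4.81e-05	0.003258
hsa-mir-99b	15188.00	33816.70	1.372	up	5.51e-05	0.003362
hsa-mir-193a	602.00	1560.30	1.450	up	0.000106	0.005878
hsa-mir-125a	14865.00	32322.00	1.231	up	0.000195	0.009918
hsa-mir-7151	67817.00	24552.00	-1.317	down	0.000415	0.019461
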