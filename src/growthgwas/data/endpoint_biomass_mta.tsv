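trait	marker_id	chromosome	position	maf	p_value	p_value_fdr	effect	pve_pct
fresh_weight	Bn-A04-p4409752	A04	5462587	0.4937	1.89e-08	0.0002	1.0762	8.64
fresh_weight	Bn-A01-p7850092	A05	1595585	0.0430	8.62e-07	0.0028	-2.6757	4.01
fresh_weight	Bn-A07-p9632473	A07	15644870	0.2715	1.05e-05	0.0191	-0.9127	5.07
fresh_weight	Bn-A07-p5114831	A08	5664005	0.3637	5.54e-08	0.0003	0.9170	1.75
fresh_weight	Bn-A08-p16771030	A08	26455071	0.2966	4.72e-09	0.0001	-1.2357	1.37
fresh_weight	Bn-A10-p10672359	A10	10601845	0.3019	9.28e-06	0.0191	0.8144	0.02
fresh_weight	Bn-A10-p13343454	A10	12120357	0.2117	1.48e-07	0.0006	-1.1502	2.16
fresh_weight	Bn-scaff_16116_1-p487063_del	C02	25078453	0.0629	3.01e-05	0.0377	-0.8749	0.33
fresh_weight	Bn-scaff_18702_1-p589589	C02	27593710	0.0639	8.45e-06	0.0191	-1.4439	1.21
fresh_weight	Bn-scaff_16545_1-p862530	C02	50263120	0.4874	1.05e-05	0.0191	-0.8823	1.51
fresh_weight	Bn-scaff_21705_1-p175010	C02	54034064	0.3344	1.60e-05	0.0261	0.8604	1.33
fresh_weight	Bn-scaff_16200_1-p503123	C07	17183655	0.3176	2.52e-05	0.0342	1.5186	0.57
fresh_weight	Bn-scaff_16197_1-p3022518	C08	41613071	0.2809	1.92e-05	0.0285	0.7434	0.44
dry_weight	Bn-A04-p9426523	A04	13935829	0.1908	1.71e-05	0.0466	-0.0705	2.11
dry_weight	Bn-A10-p11817272	A07	2411921	0.2002	1.63e-06	0.0066	-0.0755	4.85
dry_weight	Bn-A10-p13343454	A10	12120357	0.2117	3.05e-05	0.0709	-0.0623	3.56
dry_weight	Bn-scaff_16804_1-p178142	C02	9108149	0.1122	1.07e-07	0.0009	-0.1186	5.08
dry_weight	Bn-scaff_16545_1-p862530	C02	50263120	0.4874	4.81e-05	0.0872	-0.0411	0.00
dry_weight	Bn-scaff_21705_1-p175010	C02	54034064	0.3344	4.03e-07	0.0022	0.0736	1.48
dry_weight	Bn-scaff_21312_1-p895326	C03	11220963	0.0398	8.64e-09	0.0001	0.2735	5.91
dry_weight	Bn-scaff_15766_1-p117110	C07	14697010	0.2904	6.13e-06	0.0200	0.1230	1.47
dry_weight	Bn-A10-p10083397_del	C09	59994601	0.0273	3.70e-05	0.0755	0.1283	0.89
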