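interval	marker_id	chromosome	position	ld_block	interval_start	interval_stop	interval_size	n_genes	n_mtas	traits
1	Bn-A04-p2218115	A04	2103821	no	2003821	2203821	200000	44	14	leaf_area;biovolume
2	Bn-A10-p13343454	A10	12120357	no	12020357	12220357	200000	54	16	fresh_weight;dry_weight;leaf_area;biovolume;plant_height
3	Bn-scaff_16804_1-p178142	C02	9108149	yes	8497706	10116820	1619114	148	9	dry_weight;leaf_area;biovolume;plant_height;color_uniformity
4	Bn-scaff_21312_1-p895326	C03	11220963	no	11120963	11320963	200000	43	16	dry_weight;leaf_area;biovolume
5	Bn-scaff_16361_1-p2350469	C08	40120568	yes	39843456	40211817	368361	72	14	leaf_area;biovolume
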