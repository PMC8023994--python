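snp_id	effect_allele	beta_igf1	se_igf1	p_igf1	or_hip	se_hip	p_hip	or_knee	se_knee	p_knee	igfbp3
rs1065656	G	0.050	0.003	4e-84	0.987	0.015	0.392	1.019	0.012	0.116	1
rs2153960	A	0.048	0.003	6e-76	1.025	0.016	0.125	1.023	0.013	0.061	0
rs509035	A	0.054	0.003	5e-102	0.998	0.015	0.897	1.011	0.012	0.342	0
rs646776	T	-0.029	0.003	3e-25	0.939	0.016	2e-4	0.992	0.013	0.543	1
rs700753	G	0.113	0.002	1e-300	0.982	0.015	0.234	0.984	0.011	0.155	1
rs780093	C	0.060	0.002	1e-135	1.041	0.016	0.007	1.021	0.012	0.066	0
rs934073	G	0.035	0.003	4e-43	1.011	0.016	0.471	1.000	0.012	0.988	0
rs978458	C	-0.074	0.003	6e-172	0.953	0.015	0.003	0.983	0.012	0.180	0
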