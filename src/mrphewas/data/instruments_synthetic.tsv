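rsid	effect_allele	other_allele	eaf	beta_serum_iron	se_serum_iron	beta_log10_ferritin	se_log10_ferritin	beta_transferrin	se_transferrin	beta_transferrin_saturation	se_transferrin_saturation
rs1800562	A	G	0.07	0.328	0.016	0.204	0.014	-0.479	0.018	0.577	0.016
rs1799945	G	C	0.15	0.189	0.012	0.061	0.011	-0.252	0.014	0.231	0.013
rs855791	A	G	0.45	0.181	0.009	0.055	0.008	-0.139	0.01	0.19	0.009
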