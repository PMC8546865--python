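dataset	n_genes	n_samples	n_models_hit	n_hits	n_plastic_types	n_polymer_hits	n_additive_hits
soil_australia	78849927	46	99	11093	9	4224	6869
soil_global	21248672	261	84	6175	9	1098	5077
soil_china	6536825	6	50	851	7	273	578
ocean	107735703	139	99	11906	10	7232	4674
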