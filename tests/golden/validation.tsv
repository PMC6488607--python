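residue_class	n_sites	auc	a	b	c	d	odds_ratio	p_value
ST	147	0.796141975308642	21	6	29	91	10.982758620689655	3.063512392598153e-07
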