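family_id	start_col	end_col	n_significant	significant_cols	min_p	mean_W
F000	25	31	3	27;28;29	1.4593789598562795e-09	3.466666666666667
F001	24	29	2	26;27	9.370273846131989e-09	2.9
F002	24	29	2	26;27	7.993570098608914e-09	3.2
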