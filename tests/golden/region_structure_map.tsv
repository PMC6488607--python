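family_id	structure_id	start_col	end_col	residues	unmapped_columns	covered
F000	synthetic_F000_A	25	31	25;26;27;28;29;30;31		True
F001	synthetic_F001_A	24	29	24;25;26;27;28;29		True
F002	synthetic_F002_A	24	29	22;23;24;25;26;27		True
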