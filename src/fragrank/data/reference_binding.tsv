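pdb	ic50_nM	be_kcal_mol	le_printed	bei_printed	le_erratum
1W51	500	-10.55	0.377	20.67	false
2P83	11	-10.96	0.391	21.47	false
3L58	15-80	-11.84	0.377	23.20	true
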