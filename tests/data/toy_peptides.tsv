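peptide_id	protein_id	origin	unique_mapping
p01	P1_HUMAN	human	True
p02	P1_HUMAN	human	True
p03	P2_HUMAN	human	True
p04	P2_HUMAN	human	True
p05	P3_HUMAN	human	True
p06	P3_HUMAN	human	True
p07	P4_HUMAN	human	True
p08	P4_HUMAN	human	True
p09	P5_HUMAN	human	True
p10	P5_HUMAN	human	True
p11	P6_HUMAN	human	True
p12	P6_HUMAN	human	True
p13	P7_HUMAN	human	True
p14	P7_HUMAN	human	True
p15	P8_HUMAN	human	True
p16	P8_HUMAN	human	True
p17	PY1_YEAST	yeast	True
p18	PY1_YEAST	yeast	True
p19	IRT1	iRT	True
p20	P9_HUMAN	human	True
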