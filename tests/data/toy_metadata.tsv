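run_id	instrument	day	sample_type
A1	MS1	1	A
A2	MS2	1	A
A3	MS1	2	A
B1	MS1	1	B
B2	MS2	2	B
B3	MS2	2	B
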