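reference	position	subfamily	base
L1_consensus	190	L1-HS	G
L1_consensus	190	L1-PA2	A
L1_consensus	190	L1-PA3	A
L1_consensus	190	L1-PA4	A
L1_consensus	190	L1-PA5	A
L1_consensus	205	L1-HS	C
L1_consensus	205	L1-PA2	C
L1_consensus	205	L1-PA3	T
L1_consensus	205	L1-PA4	T
L1_consensus	205	L1-PA5	C
L1_consensus	220	L1-HS	T
L1_consensus	220	L1-PA2	T
L1_consensus	220	L1-PA3	T
L1_consensus	220	L1-PA4	C
L1_consensus	220	L1-PA5	C
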