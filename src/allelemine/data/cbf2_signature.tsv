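paralog	offset_bp	allele
morex_CBF2a	63	A
morex_CBF2a	260	C
morex_CBF2a	632	G
morex_CBF2a	770	T
morex_CBF2a	841	A
morex_CBF2a	920	G
nure_CBF2a	63	A
nure_CBF2a	260	T
nure_CBF2a	632	G
nure_CBF2a	770	C
nure_CBF2a	841	A
nure_CBF2a	920	G
nure_CBF2b	63	G
nure_CBF2b	260	C
nure_CBF2b	632	G
nure_CBF2b	770	T
nure_CBF2b	841	T
nure_CBF2b	920	G
CBF2ab_fusion	63	G
CBF2ab_fusion	260	T
CBF2ab_fusion	632	G
CBF2ab_fusion	770	C
CBF2ab_fusion	841	T
CBF2ab_fusion	920	G
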