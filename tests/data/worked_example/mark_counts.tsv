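	FW13/14	adult	FW15/16	unique
H3K27ac	1	1	0	1
H3K4me1	1	0	1	2
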