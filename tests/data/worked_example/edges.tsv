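ucne	gene	distance	distance_bin	tad_consistent
U1	GA	-10000	5-50kb	True
U1	GB	29700	5-50kb	False
U2	GA	-30000	5-50kb	True
U2	GB	9650	5-50kb	False
U4	GB	-30000	5-50kb	True
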