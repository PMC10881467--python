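ucne	gene	distance	distance_bin	tad_consistent	panel	phenotype
U1	GB	29700	5-50kb	False	Eye	retinal dystrophy
U2	GB	9650	5-50kb	False	Eye	retinal dystrophy
U4	GB	-30000	5-50kb	True	Eye	retinal dystrophy
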