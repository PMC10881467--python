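ucne	domain_targets	linkage_targets	relation
U1	GA,GB	GA,GB	identical
U2	GA,GB		disjoint
U4	GB	GC	disjoint
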