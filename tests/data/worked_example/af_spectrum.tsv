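bin	ucne_count	ucne_proportion	background_count	background_proportion	proportion_ratio	density_ratio
ultrarare	3	0.6	1	1.0	0.6	131.25
very_rare	0	0.0	0	0.0		
rare	1	0.2	0	0.0		
low_frequency	0	0.0	0	0.0		
common	1	0.2	0	0.0		
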