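variant	bin	is_sv	ucne	enhancer_state	genes	carriers
chr1:20101:T>C	ultrarare	False	U1	sustained_adult	GA,GB	case_0001
chr1:79001-81000:DUP	ultrarare	True	U4	open_only	GB	case_0002
chr1:80051:G>A	ultrarare	False	U4	open_only	GB	case_0002
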