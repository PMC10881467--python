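variant	bin	is_sv	ucne	enhancer_state	genes	carriers
chr1:20101:T>C	ultrarare	False	U1	sustained_adult	GA,GB	case_0001
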