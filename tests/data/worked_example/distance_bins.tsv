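bin	count
0-5kb	0
5-50kb	6
50-500kb	0
>500kb	0
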