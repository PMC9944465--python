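alias	canonical
ABL	ABL1
HER4	ERBB4
HER2	ERBB2
RON	MST1R
FAK	PTK2
YES	YES1
MEK1	MAP2K1
MEK2	MAP2K2
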