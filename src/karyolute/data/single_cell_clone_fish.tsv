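cell_line	sample	is_clone	probe	modal_n	nonmodal_pct
fibroblasts	control	0	CEP11	2	0.5
fibroblasts	control	0	CEP17	2	0
fibroblasts	control	0	CEP18	2	0
fibroblasts	control	0	1p	2	0
fibroblasts	control	0	17q	2	0
GI-MEN	mother	0	CEP11	2	51
GI-MEN	mother	0	CEP17	2	36
GI-MEN	mother	0	CEP18	3	23
GI-MEN	mother	0	1p	2	8
GI-MEN	mother	0	17q	2	48
GI-MEN	F5	1	CEP11	5	8
GI-MEN	F5	1	CEP17	2	5
GI-MEN	F5	1	CEP18	2	12
GI-MEN	F5	1	1p	2	5
GI-MEN	F5	1	17q	5	34
GI-MEN	A9	1	CEP11	6	30
GI-MEN	A9	1	CEP17	2	9
GI-MEN	A9	1	CEP18	4	23
GI-MEN	A9	1	1p	2	18
GI-MEN	A9	1	17q	6	43
GI-MEN	D3	1	CEP11	5	5
GI-MEN	D3	1	CEP17	2	12
GI-MEN	D3	1	CEP18	4	21
GI-MEN	D3	1	1p	2	1
GI-MEN	D3	1	17q	5	42
SK-N-AS	mother	0	CEP11	2	14
SK-N-AS	mother	0	CEP17	1	26
SK-N-AS	mother	0	CEP18	3	32
SK-N-AS	mother	0	1p	2	16
SK-N-AS	mother	0	17q	4	73
SK-N-AS	C8	1	CEP11	2	11
SK-N-AS	C8	1	CEP17	1	6
SK-N-AS	C8	1	CEP18	2	13
SK-N-AS	C8	1	1p	2	10
SK-N-AS	C8	1	17q	4	66
SK-N-AS	E7	1	CEP11	2	5
SK-N-AS	E7	1	CEP17	1	6
SK-N-AS	E7	1	CEP18	2	8
SK-N-AS	E7	1	1p	2	12
SK-N-AS	E7	1	17q	4	50
SK-N-AS	C5	1	CEP11	2	5
SK-N-AS	C5	1	CEP17	1	6
SK-N-AS	C5	1	CEP18	2	8
SK-N-AS	C5	1	1p	2	12
SK-N-AS	C5	1	17q	4	50
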