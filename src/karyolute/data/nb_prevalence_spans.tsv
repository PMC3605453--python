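case_id	subtype	ploidy	n_segments	n_numerical	n_structural	span_pct
ITCC35	1	2n-3n	8	8	0	5
NRC1	1	3n-5n	15	15	0	10
NRC10	1	3n-4n	13	13	0	10
NRC3	1	3n	7	7	0	13
ITCC44	1	2n-3n	12	11	2	15
ITCC111	1	2n-3n	11	11	0	16
NRC5	1	2n-3n	10	10	0	20
ITCC9	1	2n-3n	11	11	0	23
ITCC2	1	3n	12	10	2	30
ITCC38	1	2n-3n	14	12	2	65
SK-N-SH	2A	2n	5	1	4	26
ITCC130	2A	2n	11	0	11	42
ITCC10	2A	2n	6	0	6	45
NRC13	2A	4n	9	6	3	46
NRC14	2A	4n	9	0	9	48
ITCC36	2A	2n	10	1	9	50
NRC7	2A	2n	14	10	4	50
ITCC29	2A	2n	5	0	5	56
ITCC13	2A	2n	13	2	10	62
SK-N-AS	2A	2n	19	3	16	71
NRC8	2B	4n	6	4	2	7
NRC4	2B	2n	4	0	4	19
IMR32	2B	2n	10	1	9	23
SKNBE	2B	4n	26	6	20	29
NRC11	2B	2n	4	0	4	35
ITCC31	2B	2n	6	2	4	38
LAN1	2B	4n	25	7	18	46
GI-MEN	2B	4n	22	4	18	61
SK-N-FI	2B	2n	17	1	16	64
ITCC174	2B	2n	6	0	6	72
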