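clade	subfamily	n_genes	n_scaffold	n_degenerate	intact	partial	pseudogene	truncated
gamma-c	14j1-like	73	9	64	9	4	5	55
gamma-c	14A16-like	58	13	45	6	5	5	42
gamma-c	14I1-like	7	2	5	0	5	0	2
gamma-c	14C36-like	47	6	41	2	4	3	38
gamma-c	14A2-like	1	1	0	0	0	0	1
gamma	5v1-like	1	1	0	1	0	0	0
gamma	5F1-like	2	2	0	1	1	0	0
gamma	24-like	1	0	1	0	0	0	1
gamma	4a16-like	2	1	1	0	0	0	2
gamma	6B1-like	1	1	0	1	0	0	0
gamma	13c2-like	2	0	2	0	0	0	2
gamma	11a1-like	1	1	0	0	1	0	0
gamma	10ag1-like	10	1	9	0	3	2	5
unknown	unknown	14	0	14	0	0	0	12
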