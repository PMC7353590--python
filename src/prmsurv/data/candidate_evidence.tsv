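sequence	segment	modification	missed_cleavages	det_2	det_5	det_10	det_15	det_20	det_25	mean_abundance
APKLLIYDTSKLASGVPSR	VL	acetylation	2	0	0	0	0	4	4	310000
DIQMTQSPSTLSASVGDR	VL		0	0	3	4	4	4	4	1500000
LLIYDTSKLASGVPSR	VL		1	0	0	0	3	4	4	750000
LLIYDTSK	VL		0	4	4	4	4	4	4	5200000
LASGVPSR	VL		0	0	1	1	3	2	2	180000
VTNMDPADTATYYCAR	VH	carbamidomethyl	0	4	4	4	4	4	4	2100000
LTISKDTSKNQVVLK	VH		2	0	0	0	2	4	3	260000
KDYNPSLK	VH	acetylation	1	0	3	4	4	4	4	980000
SRLTISK	VH	phosphorylation	1	0	0	4	4	4	4	640000
NQVVLK	VH		0	0	0	2	4	4	4	500000
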