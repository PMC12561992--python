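# Reaction rules (Netflux-style): '!' = inhibiting input, '&' = AND gate,
# rows sharing a target combine by OR. Row 1 is the external glucose stimulus
# (its weight is the normalized glucose schedule). The disease variant is
# shipped; the healthy variant flips '!RhoRock => MLCP' to activating.
id	rule	W	n	EC50
1	=> GLU	1.0	1.4	0.5
2	GLU => AGE	1.0	1.4	0.5
3	AGE => RAGEec	1.0	1.4	0.5
4	RAGEec => NADPHec	1.0	1.4	0.5
5	NADPHec => ROSec	1.0	1.4	0.5
6	ROSec => NFkBec	1.0	1.4	0.5
7	IL1R => PI3K	1.0	1.4	0.5
8	NFkBec => IL1b	1.0	1.4	0.5
9	IL1b => IL1R	1.0	1.4	0.5
10	IL1R => NFkB	1.0	1.4	0.5
11	NFkB => IL1b	1.0	1.4	0.5
12	NFkB => VEGFAmRNA	1.0	1.4	0.5
13	NFkB => IL6	1.0	1.4	0.5
14	NFkB => TNFa	1.0	1.4	0.5
15	VEGFAmRNA => VEGFA	1.0	1.4	0.5
16	VEGFA => VEGFR1	1.0	1.4	0.5
17	VEGFA => VEGFR2	1.0	1.4	0.5
18	VEGFR2 => RhoRock	1.0	1.4	0.5
19	RhoRock => pMLC	1.0	1.4	0.5
20	!RhoRock => MLCP	1.0	1.4	0.5
21	MLCK & MLC => pMLC	1.0	1.4	0.5
22	MLCP & pMLC => MLC	1.0	1.4	0.5
23	MLC => Actin_r	1.0	1.4	0.5
24	pMLC => Actin_s	1.0	1.4	0.5
25	AGE => RAGE	1.0	1.4	0.5
26	RAGE => NADPH	1.0	1.4	0.5
27	NADPH => ROS	1.0	1.4	0.5
28	ROS => NFkB	1.0	1.4	0.5
29	VEGFR2 => PI3K	1.0	1.4	0.5
30	VEGFR1 => PI3K	1.0	1.4	0.5
31	PI3K => AKT	1.0	1.4	0.5
32	AKT => eNOS	1.0	1.4	0.5
33	VEGFR2 => PLCg	1.0	1.4	0.5
34	PLCg => Ca	1.0	1.4	0.5
35	Ca => eNOS	1.0	1.4	0.5
36	eNOS => NO	1.0	1.4	0.5
37	NO & ROSec => ONOO	1.0	1.4	0.5
38	Ca => MLCK	1.0	1.4	0.5
39	!NO => MLCK	1.0	1.4	0.5
40	ONOO => pJunction	1.0	1.4	0.5
41	ROSec => pJunction	1.0	1.4	0.5
42	TNFa => pJunction	1.0	1.4	0.5
43	IL6 => pJunction	1.0	1.4	0.5
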