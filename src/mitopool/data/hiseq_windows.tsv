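start	end	max_divergence_percent
0	1076	22
976	2855	21
2779	4036	20
3823	5073	24
4973	5461	20
5361	7146	18
7043	7837	19
7787	8076	27
8004	8753	24
8653	9604	19
9537	10328	26
10228	11789	24
11689	14214	24
14114	15427	21
15327	16440	35
16087	354	30
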