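specimen	platform	A	C	G	T	N	insertions_added	total_bp
UMMZ240023	iontorrent	4	1	0	2	8	0	5406
UMMZ240022	iontorrent	11	5	2	12	16	5	10746
UMMZ192977	iontorrent	6	5	2	10	6	0	9593
UMMZ192977	r454	1	3	0	2	2	0	15540
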