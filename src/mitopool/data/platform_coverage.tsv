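species	sample	platform	reads_used	mean_read_len
G_alternans	RAN31062	miseq	6008	448
G_larvata	UMMZ240023	hiseq	442600	95
G_larvata	UMMZ240023	r454	2481	523
G_larvata	UMMZ240023	iontorrent	264	98
G_larvata	RAN31203	miseq	562	448
H_rostratus	RAN31219	miseq	284	448
G_alternans	UMMZ240022	hiseq	512609	95
G_alternans	UMMZ240022	r454	1178	523
G_alternans	UMMZ240022	iontorrent	367	98
G_sechellensis	UMMZ193076	miseq	1655	448
G_alternans	UMMZ192945	miseq	583	448
H_brevis	UMMZ192977	miseq	3092	448
H_brevis	UMMZ192977	hiseq	670560	95
H_brevis	UMMZ192977	r454	2148	523
H_brevis	UMMZ192977	iontorrent	375	98
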