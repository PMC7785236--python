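subject	condition	tau	xmin_s	xmax_s	alpha	xmin_d	xmax_d	exp_rel	snz_regression	snz_collapse	complexity	rebin_ks_d	norebin_ks_d	rebin_ks_s	norebin_ks_s
813KT	awake	2.709	16	196	4.422	8	30	2.00234055	1.2529880263	1.144	0.0473942748	0.0444209518	0.1290998009	0.0623528147	0.1503449156
813KT	ketamine	2.225	6	60	3.007	4	17	1.6383673469	1.2472912656	1.221	0.0316139101	0.0259019459	0.1375173692	0.0508161703	0.1653117455
802PF	awake	2.484	13	368	4.783	9	41	2.5491913747	1.2654549163	1.262	0.0469241472	0.0395054996	0.1244217247	0.0677982829	0.1588397862
802PF	propofol	2.295	2	40	3.407	3	16	1.8586872587	1.2407987895	1.271	0.0036012452	0.0297453155	0.1134300394	0.0788062334	0.1661862264
730PF	awake	2.834	14	316	3.679	7	32	1.4607415485	1.3887947163	1.377	0.0470132706	0.0378105651	0.1299924942	0.0556711293	0.1639426327
730PF	propofol	2.299	2	56	2.446	1	8	1.1131639723	1.4430822801	1.508	0.0051650643	0.0252161665	0.0926269857	0.0729665868	0.1340633845
719KT	awake	2.93	22	634	4.029	8	67	1.5694300518	1.405535723	-1.1	0.0477691165	0.0346876135	0.12823451	0.063741846	0.1690890631
719KT	ketamine	2.93	22	634	4.029	8	67	1.5694300518	1.2537008081	1.25	0.029773869	0.0261199899	0.1324190428	0.0550677446	0.1445344283
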