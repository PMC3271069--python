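# SYNTHETIC reference table: reproduces the curated lignocellulose ROI database's
# class structure (42 lignin-aromatic, 17 lignin-aliphatic, 26 hemicellulose,
# 3 uncategorized) with class-typical HSQC shift ranges; individual centers are
# generated (ecomics.fixtures.gen_roi_database, seed 20120301), not literature values.
id	h_center	c_center	signal_class	detailed_category	color_group
roi001	6.9618	125.0704	lignin-aromatic	Syringyl	brown
roi002	7.4222	118.0286	lignin-aromatic	Syringyl (oxidized alpha-ketone)	brown
roi003	7.2356	117.9299	lignin-aromatic	Guaiacyl	brown
roi004	6.4336	108.4395	lignin-aromatic	Guaiacyl (oxidized alpha-ketone)	brown
roi005	7.6992	102.4025	lignin-aromatic	p-Hydroxyphenyl	brown
roi006	6.3338	134.3804	lignin-aromatic	Ferulate	brown
roi007	6.6530	129.1172	lignin-aromatic	p-Coumarates	brown
roi008	7.2018	110.5450	lignin-aromatic	Cinnamyl alcohol end group	brown
roi009	6.0330	120.0162	lignin-aromatic	p-Hydroxybenzoates	brown
roi010	6.0287	125.2878	lignin-aromatic	Syringyl	brown
roi011	7.8268	112.5571	lignin-aromatic	Syringyl (oxidized alpha-ketone)	brown
roi012	7.1975	124.6699	lignin-aromatic	Guaiacyl	brown
roi013	7.8977	121.4388	lignin-aromatic	Guaiacyl (oxidized alpha-ketone)	brown
roi014	7.9580	103.6353	lignin-aromatic	p-Hydroxyphenyl	brown
roi015	6.1486	100.9648	lignin-aromatic	Ferulate	brown
roi016	6.6550	118.2659	lignin-aromatic	p-Coumarates	brown
roi017	6.8585	119.0093	lignin-aromatic	Cinnamyl alcohol end group	brown
roi018	6.3205	127.2519	lignin-aromatic	p-Hydroxybenzoates	brown
roi019	6.7216	123.9756	lignin-aromatic	Syringyl	brown
roi020	6.6072	121.0524	lignin-aromatic	Syringyl (oxidized alpha-ketone)	brown
roi021	6.2277	132.9133	lignin-aromatic	Guaiacyl	brown
roi022	6.1414	119.1531	lignin-aromatic	Guaiacyl (oxidized alpha-ketone)	brown
roi023	6.4748	114.9916	lignin-aromatic	p-Hydroxyphenyl	brown
roi024	6.3321	119.2414	lignin-aromatic	Ferulate	brown
roi025	6.9191	114.0171	lignin-aromatic	p-Coumarates	brown
roi026	7.4224	129.6166	lignin-aromatic	Cinnamyl alcohol end group	brown
roi027	6.0458	102.0311	lignin-aromatic	p-Hydroxybenzoates	brown
roi028	7.7749	126.3015	lignin-aromatic	Syringyl	brown
roi029	7.7416	119.2095	lignin-aromatic	Syringyl (oxidized alpha-ketone)	brown
roi030	6.1613	112.3888	lignin-aromatic	Guaiacyl	brown
roi031	7.3763	127.5821	lignin-aromatic	Guaiacyl (oxidized alpha-ketone)	brown
roi032	6.7866	103.7701	lignin-aromatic	p-Hydroxyphenyl	brown
roi033	6.8636	122.5172	lignin-aromatic	Ferulate	brown
roi034	7.4882	123.5104	lignin-aromatic	p-Coumarates	brown
roi035	6.7593	114.3486	lignin-aromatic	Cinnamyl alcohol end group	brown
roi036	6.3891	103.9582	lignin-aromatic	p-Hydroxybenzoates	brown
roi037	6.9867	101.7863	lignin-aromatic	Syringyl	brown
roi038	6.3800	121.9200	lignin-aromatic	Syringyl (oxidized alpha-ketone)	brown
roi039	7.7806	123.8140	lignin-aromatic	Guaiacyl	brown
roi040	6.9723	117.0007	lignin-aromatic	Guaiacyl (oxidized alpha-ketone)	brown
roi041	6.9550	105.6476	lignin-aromatic	p-Hydroxyphenyl	brown
roi042	7.3593	110.5598	lignin-aromatic	Ferulate	brown
roi043	3.1871	74.2463	lignin-aliphatic	β-O-4	red
roi044	3.6505	58.3204	lignin-aliphatic	β-O-4-S	red
roi045	4.1159	72.0707	lignin-aliphatic	β-O-4-H/G	red
roi046	3.3911	73.4622	lignin-aliphatic	β-5	red
roi047	4.6275	85.2108	lignin-aliphatic	β-β	red
roi048	3.4571	58.5113	lignin-aliphatic	5-5/4-O-β	red
roi049	5.6353	73.8896	lignin-aliphatic	β-O-4	red
roi050	5.1380	89.2116	lignin-aliphatic	β-O-4-S	red
roi051	4.6545	80.6682	lignin-aliphatic	β-O-4-H/G	red
roi052	3.0496	58.9332	lignin-aliphatic	β-5	red
roi053	3.5765	89.9407	lignin-aliphatic	β-β	red
roi054	5.7957	57.4959	lignin-aliphatic	5-5/4-O-β	red
roi055	3.8545	54.5978	lignin-aliphatic	β-O-4	red
roi056	4.1162	58.9359	lignin-aliphatic	β-O-4-S	red
roi057	4.2048	52.3867	lignin-aliphatic	β-O-4-H/G	red
roi058	3.4056	50.7885	lignin-aliphatic	β-5	red
roi059	5.7553	67.3038	lignin-aliphatic	β-β	red
roi060	4.8623	99.7535	hemicellulose	Acetylated xylopyranoside	green
roi061	4.2698	85.3726	hemicellulose	Xylopyranoside	blue
roi062	3.4071	102.4881	hemicellulose	Xylopyranoside+glucopyranoside	purple
roi063	5.2728	85.3116	hemicellulose	Glucopyranoside	green
roi064	3.2494	85.8515	hemicellulose	Galactopyranoside	blue
roi065	4.4270	105.5645	hemicellulose	Arabinofuranoside	purple
roi066	5.2013	63.6133	hemicellulose	Mannopyranoside	green
roi067	4.6833	105.0331	hemicellulose	Fucopyranoside	blue
roi068	4.3494	77.5807	hemicellulose	Methyl-glucuronic acid	purple
roi069	5.0277	108.1800	hemicellulose	Acetylated xylopyranoside	green
roi070	3.3124	79.2694	hemicellulose	Xylopyranoside	blue
roi071	3.7998	69.4423	hemicellulose	Xylopyranoside+glucopyranoside	purple
roi072	3.4585	83.4124	hemicellulose	Glucopyranoside	green
roi073	4.2742	87.9153	hemicellulose	Galactopyranoside	blue
roi074	4.0167	72.6923	hemicellulose	Arabinofuranoside	purple
roi075	4.6885	101.3180	hemicellulose	Mannopyranoside	green
roi076	3.2842	60.1012	hemicellulose	Fucopyranoside	blue
roi077	4.4722	88.6798	hemicellulose	Methyl-glucuronic acid	purple
roi078	3.9464	75.5491	hemicellulose	Acetylated xylopyranoside	green
roi079	4.9829	84.7442	hemicellulose	Xylopyranoside	blue
roi080	4.9615	80.0246	hemicellulose	Xylopyranoside+glucopyranoside	purple
roi081	4.2777	90.1681	hemicellulose	Glucopyranoside	green
roi082	4.3467	89.0587	hemicellulose	Galactopyranoside	blue
roi083	4.7491	82.0779	hemicellulose	Arabinofuranoside	purple
roi084	4.0569	102.7210	hemicellulose	Mannopyranoside	green
roi085	3.4484	100.0003	hemicellulose	Fucopyranoside	blue
roi086	1.8594	24.1078	uncategorized	Uncategorized	grey
roi087	1.2768	31.6158	uncategorized	Uncategorized	grey
roi088	2.3776	18.0476	uncategorized	Uncategorized	grey
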