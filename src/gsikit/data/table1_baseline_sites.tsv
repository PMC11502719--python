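no	site	abbr	lat	lon	year	n	status	population	n_pop
1	Gulf of Riga	BASH_GR	58.02	23.50	2014	46	known	BASH	102
2	Bornholm Basin	BASH_CB	55.26	15.33	2016	38	known	BASH
3	Western Baltic Sea (Ruegen)	BASH_RU	54.21	13.42	2019	18	known	BASH
4	Vistula Lagoon (Gdansk)	CBSS_GD	54.37	19.67	2009	70	known	CBSS	82
5	Gulf of Finland	CBSS_GF	60.40	26.70	2009	41	known	CBSS
6	Southern Bight	Downs	51.63	1.68	2016	104	known	Downs	104
7	North Sea	NSAS	59.21	-2.38	2011	60	known	NSAS	60
8	Norwegian Sea	NSS	67.12	11.74	2021	140	known	NSS	140
9	Kattegat	WBSS_KA	55.73	11.37	2009	40	known	WBSS	122
10	Ringkoebing Fjord	WBSS_RF	55.97	8.24	2009	38	known	WBSS
11	Western Baltic Sea (Ruegen)	WBSS_RU	54.21	13.62	2009	45	known	WBSS
12	Skagerrak East (Oeckeroe)	WBSS_SKE	57.60	11.40	2009	42	known	WBSS-SK	63
13	Skagerrak West (Hoevaag)	WBSS_SKW	58.15	8.27	2015	24	known	WBSS-SK
14	The Minch, West of Scotland	Sp-6aN	57.81	-5.87	2018	29	known	Sp-6a	58
15	Donegal	Sp-6aS	55.31	-7.75	2022	29	known	Sp-6a
16	Rossfjordvannet	ROSSFJ	69.32	18.27	2015	18	known	Pacific-Hybrids	30
17	Balsfjorden	BALSFJ	69.18	19.22	2015	12	known	Pacific-Hybrids
18	Gloppenfjorden	GLOPFJ	61.78	6.17	2013	12	known	Local-Fjords	108
19	Lindaaspollen	Lindas	60.73	5.13	2010	35	known	Local-Fjords
20	Lustrafjorden	LUFJ	61.34	7.37	2011, 2021	82	known	Local-Fjords
21	Sognefjorden	SOGNEFJ	61.11	6.38	2015	28	known	Local-Fjords
22	Trondheimsfjorden	THF	63.80	11.00	2020	205	known	THF	100
23	North Atlantic (Faroe Islands)	FASH	61.02	-6.38	2009	34	known	NASS	129
24	North Atlantic (Iceland)	ISSH	63.75	-16.39	2009, 2010	476	known	NASS
25	North Atlantic (Lofoten)	NASH	68.20	14.50	2019	97	new	NASS
26	Kirkefjorden	KIRKFJ	68.00	13.00	2021	94	new
27	Austefjorden	AUFJ	62.10	6.31	2020	119	new
28	Dalsfjorden	DAFJ	62.00	5.83	2020	76	new
29	Gursken	GURS	62.20	5.63	2021	68	new
30	Hjoerundfjorden	HJFJ	62.10	6.54	2020	111	new
31	Romsdalsfjorden	ROMSFJ	62.70	7.50	2019	32	new
32	Sykkylven	SYKK	62.40	6.56	2020, 2022	136	new
33	Volda	VOL	62.10	6.07	2020	39	new
34	NSS-Strandfjorden	NSS-SF	58.30	8.53	2015	30	new
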