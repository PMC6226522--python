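# Integrin-binding motif annotations for the bundled SYNTHETIC
# stand-in chains (not natural-sequence coordinates).  Locations
# are lattice-derived under the schematic preset.
chain	start	end	sequence	segment	axial_nm	region	affinity_class
alpha1	17	22	GPOGER	D1	0.7	overlap	moderate
alpha1	38	43	GPAGEO	D1	6.7	overlap	moderate
alpha1	65	70	GPOGER	D1	14.4	overlap	moderate
alpha1	86	91	GPAGEO	D1	20.4	overlap	moderate
alpha1	113	118	GPOGER	D1	28.2	overlap	moderate
alpha1	134	139	GPAGEO	D1	34.2	gap	moderate
alpha1	161	166	GPOGER	D1	41.9	gap	moderate
alpha1	182	187	GPAGEO	D1	47.9	gap	moderate
alpha1	209	214	GPOGER	D1	55.6	gap	moderate
alpha1	230	235	GPAGEO	D1	61.6	gap	moderate
alpha1	257	262	GPOGER	D2	2.4	overlap	moderate
alpha1	278	283	GPAGEO	D2	8.4	overlap	moderate
alpha1	305	310	GPOGER	D2	16.1	overlap	moderate
alpha1	326	331	GPAGEO	D2	22.1	overlap	moderate
alpha1	353	358	GPOGER	D2	29.8	overlap	moderate
alpha1	374	379	GPAGEO	D2	35.8	gap	moderate
alpha1	401	406	GPOGER	D2	43.5	gap	moderate
alpha1	422	427	GPAGEO	D2	49.5	gap	moderate
alpha1	449	454	GPOGER	D2	57.3	gap	moderate
alpha1	470	475	GPAGEO	D2	63.3	gap	moderate
alpha1	497	502	GPOGER	D3	4.0	overlap	moderate
alpha1	518	523	GPAGEO	D3	10.0	overlap	moderate
alpha1	545	550	GPOGER	D3	17.7	overlap	moderate
alpha1	566	571	GPAGEO	D3	23.7	overlap	moderate
alpha1	593	598	GPOGER	D3	31.5	gap	moderate
alpha1	614	619	GPAGEO	D3	37.5	gap	moderate
alpha1	641	646	GPOGER	D3	45.2	gap	moderate
alpha1	662	667	GPAGEO	D3	51.2	gap	moderate
alpha1	689	694	GPOGER	D3	58.9	gap	moderate
alpha1	710	715	GPAGEO	D3	64.9	gap	moderate
alpha1	737	742	GPOGER	D4	5.6	overlap	moderate
alpha1	758	763	GPAGEO	D4	11.6	overlap	moderate
alpha1	785	790	GPOGER	D4	19.4	overlap	moderate
alpha1	806	811	GPAGEO	D4	25.4	overlap	moderate
alpha1	818	823	GQRGER	D4	28.8	overlap	high
alpha1	833	838	GPOGER	D4	33.1	gap	moderate
alpha1	854	859	GPAGEO	D4	39.1	gap	moderate
alpha1	881	886	GPOGER	D4	46.8	gap	moderate
alpha1	902	907	GPAGEO	D4	52.8	gap	moderate
alpha1	929	934	GPOGER	D4	60.5	gap	moderate
alpha1	950	955	GPAGEO	D4	55.4	gap	moderate
alpha1	977	982	GPOGER	D5	7.3	overlap	moderate
alpha1	998	1003	GPAGEO	D5	13.3	overlap	moderate
alpha1	1025	1030	GPOGER	D5	21.0	overlap	moderate
alpha1	1046	1051	GPAGEO	D5	27.0	overlap	moderate
alpha2	20	25	GAVGER	D1	2.1	overlap	moderate
alpha2	68	73	GAVGER	D1	15.9	overlap	moderate
alpha2	116	121	GAVGER	D1	29.6	overlap	moderate
alpha2	164	169	GAVGER	D1	43.3	gap	moderate
alpha2	212	217	GAVGER	D1	57.1	gap	moderate
alpha2	260	265	GAVGER	D2	3.8	overlap	moderate
alpha2	308	313	GAVGER	D2	17.5	overlap	moderate
alpha2	356	361	GAVGER	D2	31.2	gap	moderate
alpha2	404	409	GAVGER	D2	45.0	gap	moderate
alpha2	452	457	GAVGER	D2	58.7	gap	moderate
alpha2	500	505	GAVGER	D3	5.4	overlap	moderate
alpha2	548	553	GAVGER	D3	19.2	overlap	moderate
alpha2	596	601	GAVGER	D3	32.9	gap	moderate
alpha2	644	649	GAVGER	D3	46.6	gap	moderate
alpha2	692	697	GAVGER	D3	60.3	gap	moderate
alpha2	740	745	GAVGER	D4	7.1	overlap	moderate
alpha2	788	793	GAVGER	D4	20.8	overlap	moderate
alpha2	836	841	GAVGER	D4	34.5	gap	moderate
alpha2	884	889	GAVGER	D4	48.2	gap	moderate
alpha2	932	937	GAVGER	D4	62.0	gap	moderate
alpha2	980	985	GAVGER	D5	8.7	overlap	moderate
alpha2	1028	1033	GAVGER	D5	22.4	overlap	moderate
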