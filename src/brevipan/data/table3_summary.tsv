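# Per-genome chromosomal summary of the 19 L. brevis strains (published
# study, general-features table), with the beer-spoiler flag and niche.
genome_id	chromosome_length_mbp	cds_count	trna	rrna	hypothetical_pct	assigned_pct	is_elements	gc_pct	plasmid_count	spoiler	niche_label
100D8	2.35	2228	66	15	21.2	78.8	25	46.1	3	false	silage
ATCC367	2.29	2133	65	15	20.8	79.2	34	46.2	2	false	silage
BDGP6	2.79	2674	71	15	23.1	76.9	24	46.6	0	false	gut
KB290	2.40	2308	64	15	21.4	78.6	50	46.1	9	false	food
NCTC13768	2.49	2413	65	15	15.0	85.0	3	46.0	0	false	unknown
NPS-QW-145	2.55	2406	62	13	21.5	78.5	5	45.8	0	false	food
SA-C12	2.44	2344	66	15	23.2	76.7	42	45.9	2	false	silage
SRCM101106	2.44	2379	67	15	23.0	77.0	46	45.9	4	false	food
SRCM101174	2.41	2353	68	15	24.0	76.0	37	46.1	5	false	food
TMW1.2108	2.57	2448	66	15	22.8	77.2	17	45.8	8	true	beer
TMW1.2111	2.57	2458	66	15	21.8	78.2	22	45.8	6	true	beer
TMW1.2112	2.49	2283	65	15	19.6	80.4	29	46.0	5	true	beer
TMW1.2113	2.54	2376	69	15	22.5	77.5	30	45.9	4	true	brewery
UCCLB521	2.27	2088	62	15	20.0	80.0	32	46.3	5	false	brewery
UCCLB556	2.38	2201	66	18	22.8	77.2	32	46.1	7	false	brewery
UCCLB95	2.51	2283	65	15	22.7	77.3	132	45.9	2	true	beer
UCCLBBS124	2.61	2442	66	15	21.8	78.2	60	45.8	4	true	beer
UCCLBBS449	2.58	2404	66	15	21.1	78.9	114	45.8	9	true	beer
ZLB004	2.66	2207	64	15	24.0	76.0	29	46.0	5	false	gut
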